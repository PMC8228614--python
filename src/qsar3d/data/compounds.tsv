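abbrev	full_name	smiles
DMP	dimethyl phthalate	COC(=O)c1ccccc1C(=O)OC
DEP	diethyl phthalate	CCOC(=O)c1ccccc1C(=O)OCC
DBP	di-n-butyl phthalate	CCCCOC(=O)c1ccccc1C(=O)OCCCC
DIBP	diisobutyl phthalate	CC(C)COC(=O)c1ccccc1C(=O)OCC(C)C
DHXP	di-n-hexyl phthalate	CCCCCCOC(=O)c1ccccc1C(=O)OCCCCCC
DNOP	di-n-octyl phthalate	CCCCCCCCOC(=O)c1ccccc1C(=O)OCCCCCCCC
DIOP	diisooctyl phthalate [bis(6-methylheptyl) representative isomer]	CC(C)CCCCCOC(=O)c1ccccc1C(=O)OCCCCCC(C)C
DEHP	bis(2-ethylhexyl) phthalate	CCCCC(CC)COC(=O)c1ccccc1C(=O)OCC(CC)CCCC
DNP	di-n-nonyl phthalate	CCCCCCCCCOC(=O)c1ccccc1C(=O)OCCCCCCCCC
DIDP	diisodecyl phthalate [bis(8-methylnonyl) representative isomer]	CC(C)CCCCCCCOC(=O)c1ccccc1C(=O)OCCCCCCCC(C)C
nDNOP	1-decyl 2-octyl phthalate	CCCCCCCCCCOC(=O)c1ccccc1C(=O)OCCCCCCCC
DAP	diallyl phthalate	C=CCOC(=O)c1ccccc1C(=O)OCC=C
DMEP	bis(2-methoxyethyl) phthalate	COCCOC(=O)c1ccccc1C(=O)OCCOC
DPHP	bis(2-propylheptyl) phthalate	CCCCCC(CCC)COC(=O)c1ccccc1C(=O)OCC(CCC)CCCCC
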