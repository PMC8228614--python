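abbrev,raw_value,exp_printed,role,comsia_pred,comsia_res
DEHP,0.6449,0.6449,train,0.646,-0.0011
DEP,1.2220,1.2220,test,1.140,0.082
DMP,1.1534,1.1534,train,1.151,0.0024
DMEP,1.1691,1.1691,train,1.170,-0.0009
DHXP,0.6882,0.6882,test,0.673,0.0152
DNOP,0.7129,0.7129,train,0.720,-0.0071
DBP,0.7363,0.7363,train,0.746,-0.0097
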