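abbrev,raw_value,exp_printed,role,comfa_pred,comfa_res,comsia_pred,comsia_res
DMP,6800,3.8325,train,3.791,0.0415,3.829,0.0035
DEP,8600,3.9345,test,3.89,0.0445,3.942,-0.0075
DBP,7499,3.875,train,3.955,-0.08,3.896,-0.021
DIBP,15000,4.1761,train,4.241,-0.0649,4.175,0.0011
DHXP,29600,4.4713,train,4.417,0.0543,4.45,0.0213
DNOP,47000,4.6721,train,4.647,0.0251,4.684,-0.0119
DIOP,22000,4.3424,train,4.374,-0.0316,4.339,0.0034
DEHP,30000,4.4771,train,4.475,0.0021,4.477,0.0001
DNP,21500,4.3324,train,4.458,-0.1256,4.332,0.0004
DIDP,64000,4.8062,test,4.759,0.0472,4.804,0.0022
nDNOP,45200,4.6551,train,4.604,0.0511,4.647,0.0081
DAP,656,2.8169,train,2.821,-0.0041,2.815,0.0019
DMEP,2750,3.4393,test,3.436,0.0033,3.419,0.0203
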