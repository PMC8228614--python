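abbrev,raw_value,exp_printed,role,comfa_pred,comfa_res,comsia_pred,comsia_res
DEHP,1160,3.0645,train,3.053,0.0115,3.069,-0.0045
DNP,1513,3.18,train,3.206,-0.026,3.2,0.025
DIDP,1722,3.236,train,3.232,0.004,3.094,-0.0052
DMEP,975.1,2.989,train,2.984,0.005,2.992,-0.003
DHXP,1227,3.0888,test,3.091,-0.0022,2.972,0.008
DNOP,1678,3.225,train,3.206,0.019,3.233,0.003
DPHP,954.9,2.98,test,2.992,-0.012,3.203,-0.023
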