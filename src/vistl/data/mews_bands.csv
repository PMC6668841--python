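component,variable,upper,points
systolic_bp,systolic_bp,70,3
systolic_bp,systolic_bp,81,2
systolic_bp,systolic_bp,101,1
systolic_bp,systolic_bp,200,0
systolic_bp,systolic_bp,inf,2
heart_rate,heart_rate,40,2
heart_rate,heart_rate,51,1
heart_rate,heart_rate,101,0
heart_rate,heart_rate,111,1
heart_rate,heart_rate,130,2
heart_rate,heart_rate,inf,3
resp_rate,resp_rate,9,2
resp_rate,resp_rate,15,0
resp_rate,resp_rate,21,1
resp_rate,resp_rate,30,2
resp_rate,resp_rate,inf,3
temperature,temperature,35,2
temperature,temperature,38.5,0
temperature,temperature,inf,2
consciousness,avpu_level,0.5,0
consciousness,avpu_level,1.5,1
consciousness,avpu_level,2.5,2
consciousness,avpu_level,inf,3
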