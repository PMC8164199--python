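compound,parent,log_koa,log_kow,half_life_hr
DINP,,13.585,9.37,11
DEHP,,12.557,8.39,11.7
DINP-C6H5,DINP,12.378,7.23,14.2
DEHP-F,DEHP,10.980,7.84,12.8
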