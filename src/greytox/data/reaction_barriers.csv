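compound,parent,barrier_kj_mol
DINP,,51.77
DEHP,,4.08
DINP-C6H5,DINP,5.96
DEHP-F,DEHP,0.31
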