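compound,subset,fit_value,estimated,active,error
DINP,training,5.92,0.72,0.79,-1.10
DEHP,training,5.91,0.74,0.792,-1.06
BDP,training,5.88,0.79,0.797,-1.01
BOP,training,5.87,0.80,0.82,-1.03
HEHP,training,5.87,0.81,0.798,1.01
DNOP,training,5.86,0.82,0.792,1.03
DPP,training,5.85,0.84,0.936,-1.11
BMPP,training,5.84,0.87,0.829,1.05
DCHP,training,5.82,0.90,0.845,1.07
BCHP,training,5.74,1.09,1.0,1.09
DIDP,test,5.96,0.66,0.79,-1.20
DUP,test,5.85,0.84,0.79,1.06
DNDP,test,5.82,0.90,0.79,1.13
DIPP,test,5.77,1.02,0.985,1.03
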