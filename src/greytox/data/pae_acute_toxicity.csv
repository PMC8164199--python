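compound,green_algae,daphnid,mysid,fish
DEHP,0.00157,0.01,0.000419,0.01
DIDP,0.0000758,0.000669,0.0000115,0.000787
DNOP,0.00124,0.008,0.000317,0.008
DPP,0.111,0.463,0.067,0.327
DCHP,0.045,0.206,0.023,0.155
DUP,0.0000131,0.000138,0.00000143,0.000183
BCHP,0.149,0.602,0.095,0.417
BDP,0.006,0.032,0.0019,0.028
BMPP,0.032,0.15,0.015,0.116
BOP,0.025,0.121,0.011,0.095
DINP,0.000272,0.002,0.0000526,0.002
DIPP,0.141,0.573,0.088,0.398
DNDP,0.0000598,0.00054,0.0000087,0.000646
HEHP,0.006,0.035,0.002,0.03
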