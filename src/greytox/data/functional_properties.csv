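compound,parent,total_energy_au,energy_gap_ev,frequency_cm1
DINP,,-1317.02,5.51,7.60
DEHP,,-1238.39,5.56,11.39
DINP-C6H5,DINP,-1233.51,5.18,17.73
DEHP-F,DEHP,-1298.30,5.49,5.44
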