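model,total_cost,fixed_cost,rms,correlation,configuration,features
Hypo 1,51.610,33.636,0.055,0.85,16.834,HBA;H;HA
Hypo 2,51.611,33.636,0.056,0.67,16.834,HBA;HBA;RA
Hypo 3,51.612,33.636,0.057,0.58,16.834,HBA;HBA;H
Hypo 4,51.612,33.636,0.058,0.56,16.834,HBA;HBA;RA
Hypo 5,51.613,33.636,0.059,0.60,16.834,HBA;HBA;RA
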