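compound,parent,1BA9,3DWV,3ZXX,3KDT
DINP,,97.701,66.242,74.518,142.43
DEHP,,72.054,56.532,63.789,82.86
DINP-C6H5,DINP,83.904,59.264,68.658,114.19
DEHP-F,DEHP,58.184,53.211,58.610,79.66
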