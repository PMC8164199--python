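compound,parent,green_algae,daphnid,mysid,fish
DINP,,3.5654,2.6990,4.2790,2.6990
DINP-CH3,DINP,1.2218,0.5784,1.4949,0.7100
DINP-CH2CH2CH3,DINP,1.8861,1.1612,2.3010,1.2441
DINP-CH=CH2,DINP,1.4559,0.7852,1.7696,0.8996
DINP-C6H5,DINP,2.0000,1.2676,2.3979,1.3468
DINP-OCH3,DINP,0.3251,-0.2350,0.4425,-0.0453
DINP-F,DINP,0.8356,0.2262,1.0410,0.3830
DINP-Br,DINP,1.0410,0.4056,1.3010,0.5436
DINP-SH,DINP,0.8182,0.2097,1.0223,0.3665
DINP-NO2,DINP,0.2336,-0.3193,0.3372,-0.1248
DEHP,,2.8041,2.0000,3.3778,2.0000
DEHP-CH2CH3,DEHP,3.1331,2.3010,3.7670,2.3010
DEHP-CH=CH2,DEHP,3.0400,2.2218,3.6576,2.2218
DEHP-C6H5,DEHP,3.5918,2.6990,4.3170,2.6990
DEHP-OCH3,DEHP,1.9208,1.1871,2.3010,1.2676
DEHP-F,DEHP,2.3979,1.6383,2.9208,1.6990
DEHP-Br,DEHP,2.6990,1.8239,3.1898,1.8539
DEHP-NO2,DEHP,1.8239,1.1024,2.2218,1.1871
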