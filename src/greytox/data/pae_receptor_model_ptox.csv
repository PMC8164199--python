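compound,parent,green_algae,daphnid,mysid,fish
DINP,,2.3039,1.3371,3.0064,1.8487
DINP-CH3,DINP,2.0049,2.0082,1.9758,2.3857
DINP-CH2CH2CH3,DINP,2.1938,2.9862,2.4324,1.3578
DINP-CH=CH2,DINP,1.2773,2.4678,2.9583,1.1800
DINP-C6H5,DINP,2.1943,0.394,2.0074,0.7200
DINP-OCH3,DINP,2.1396,1.9394,2.2089,3.1838
DINP-F,DINP,1.4256,2.3887,1.9745,3.1892
DINP-Br,DINP,1.3281,1.100,2.4098,2.4892
DINP-SH,DINP,1.6563,5.5234,1.9857,1.5304
DINP-NO2,DINP,1.7235,1.1611,2.1128,2.1955
DEHP,,2.4583,2.5771,2.5511,1.2037
DEHP-OCH3,DEHP,2.0141,5.3772,1.9799,1.2720
DEHP-F,DEHP,2.3623,2.2673,2.2677,0.7456
DEHP-Br,DEHP,1.7537,1.9605,5.0185,0.9164
DEHP-NO2,DEHP,1.9213,0.7316,2.7852,0.4750
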