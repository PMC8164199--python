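parent,derivative,substituent,parent_value,derivative_value
DINP,DINP-CH3,-CH3,0.7171,0.8214
DINP,DINP-CH2CH3,-CH2CH3,0.7171,0.6997
DINP,DINP-CH2CH2CH3,-CH2CH2CH3,0.7171,0.8028
DINP,DINP-CH=CH2,-CH=CH2,0.7171,0.8247
DINP,DINP-C6H5,-C6H5,0.7171,0.8124
DINP,DINP-OCH3,-OCH3,0.7171,1.1392
DINP,DINP-Cl,-Cl,0.7171,0.6761
DINP,DINP-F,-F,0.7171,1.0018
DINP,DINP-Br,-Br,0.7171,0.9851
DINP,DINP-SH,-SH,0.7171,2.2095
DINP,DINP-NO2,-NO2,0.7171,1.6933
DEHP,DEHP-CH3,-CH3,0.7441,0.7442
DEHP,DEHP-CH2CH3,-CH2CH3,0.7441,1.0099
DEHP,DEHP-CH2CH2CH3,-CH2CH2CH3,0.7441,0.7456
DEHP,DEHP-CH=CH2,-CH=CH2,0.7441,0.8410
DEHP,DEHP-C6H5,-C6H5,0.7441,0.8641
DEHP,DEHP-OCH3,-OCH3,0.7441,1.1018
DEHP,DEHP-Cl,-Cl,0.7441,0.7906
DEHP,DEHP-F,-F,0.7441,0.9070
DEHP,DEHP-Br,-Br,0.7441,0.8554
DEHP,DEHP-SH,-SH,0.7441,0.7712
DEHP,DEHP-NO2,-NO2,0.7441,0.8929
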