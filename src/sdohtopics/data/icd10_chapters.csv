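chapter,start,end
Diseases of the nervous system,G00,G99
Diseases of the circulatory system,I00,I99
Diseases of the respiratory system,J00,J99
Diseases of the digestive system,K00,K95
Diseases of the musculoskeletal system and connective tissue,M00,M99
Diseases of the genitourinary system,N00,N99
"Pregnancy, childbirth and the puerperium",O00,O9A
"Congenital malformations, deformations and chromosomal abnormalities",Q00,Q99
Neoplasms,C00,D49
Diseases of the blood and blood-forming organs and certain disorders involving the immune mechanism,D50,D89
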