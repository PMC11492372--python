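name,molecular_weight_g_per_mol,radius_nm,valence,mobility_m2_per_Vs
Li+,6.94,0.09,1,4.01e-8
F-,18.99,0.119,-1,5.74e-8
Na+,22.99,0.116,1,5.19e-8
Cl-,35.45,0.167,-1,7.91e-8
K+,39.1,0.152,1,7.62e-8
oxalic_acid,90.03,0.27,-1,
hydroquinone,110.1,0.32,-1,
ascorbic_acid,176.1,0.35,-2,
citric_acid,192.1,0.37,-3,
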