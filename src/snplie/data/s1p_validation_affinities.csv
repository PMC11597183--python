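variant,mean_dg_kcal_mol,spread_dg_kcal_mol
WT,-13.76,1.42
N101(2.60)I,-12.11,1.66
N101(2.60)K,-13.59,0.84
E121(3.29)A,-11.58,3.32
E121(3.29)Q,-12.24,3.11
W269(6.48)A,-11.18,0.94
W269(6.48)E,-14.15,2.14
R292(7.34)A,-13.48,1.72
R292(7.34)V,-13.23,1.77
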