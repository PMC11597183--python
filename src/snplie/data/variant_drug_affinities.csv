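variant,ligand,mean_dg_kcal_mol,spread_dg_kcal_mol
WT,S1P,-13.76,1.42
WT,fingolimod,-11.60,2.00
WT,siponimod,-14.62,0.37
WT,ozanimod,-8.22,0.54
WT,ponesimod,-11.25,0.40
M124(3.32)T,S1P,-13.56,1.03
M124(3.32)T,fingolimod,-11.29,0.68
M124(3.32)T,siponimod,-15.99,0.62
M124(3.32)T,ozanimod,-12.72,0.26
M124(3.32)T,ponesimod,-13.18,0.50
V132(3.40)M,S1P,-12.82,0.85
V132(3.40)M,fingolimod,-10.95,0.67
V132(3.40)M,siponimod,-16.12,1.01
V132(3.40)M,ozanimod,-12.76,0.57
V132(3.40)M,ponesimod,-13.47,0.46
F205(5.42)L,S1P,-13.51,1.54
F205(5.42)L,fingolimod,-10.83,1.19
F205(5.42)L,siponimod,-16.72,0.49
F205(5.42)L,ozanimod,-12.56,0.74
F205(5.42)L,ponesimod,-13.90,0.95
T207(5.44)I,S1P,-13.29,0.98
T207(5.44)I,fingolimod,-11.36,1.00
T207(5.44)I,siponimod,-16.55,0.55
T207(5.44)I,ozanimod,-11.85,0.54
T207(5.44)I,ponesimod,-14.06,0.32
T211(5.48)P,S1P,-13.24,0.43
T211(5.48)P,fingolimod,-11.88,0.85
T211(5.48)P,siponimod,-15.98,0.79
T211(5.48)P,ozanimod,-12.37,0.76
T211(5.48)P,ponesimod,-13.12,0.46
A293(7.35)T,S1P,-12.50,1.40
A293(7.35)T,fingolimod,-11.87,0.87
A293(7.35)T,siponimod,-16.71,0.92
A293(7.35)T,ozanimod,-12.31,0.42
A293(7.35)T,ponesimod,-14.09,0.56
A293(7.35)V,S1P,-12.67,0.78
A293(7.35)V,fingolimod,-11.72,0.99
A293(7.35)V,siponimod,-16.52,0.44
A293(7.35)V,ozanimod,-12.38,0.69
A293(7.35)V,ponesimod,-14.21,0.52
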