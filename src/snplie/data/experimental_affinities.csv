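ligand,ic50_molar,temperature_K,dg_exp_reported,source_label
S1P,1.60e-10,310.15,-13.90,assay_a
S1P,4.70e-10,310.15,-13.24,assay_b
S1P,6.70e-10,310.15,-13.02,assay_c
S1P,1.40e-9,310.15,-12.56,assay_d
S1P,1.40e-9,310.15,-12.56,assay_e
S1P,1.40e-9,310.15,-12.56,assay_f
fingolimod,2.80e-10,310.15,-13.56,assay_g
fingolimod,2.10e-9,310.15,-12.31,assay_h
fingolimod,2.20e-9,310.15,-12.29,assay_i
ponesimod,1.30e-8,310.15,-11.19,assay_j
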