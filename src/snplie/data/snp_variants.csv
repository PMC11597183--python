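rsid,variant_code,frequency,impact
rs1299231517,M124(3.32)T,0.000004,possibly damaging
rs1323297044,V132(3.40)M,0.000004,probably damaging
rs1223284736,F205(5.42)L,0.000004,possibly damaging
rs1202284551,T207(5.44)I,0.00011,benign
rs1209378712,T211(5.48)P,0.000008,possibly damaging
rs201200746,A293(7.35)T,0.000004,benign
rs1461490142,A293(7.35)V,0.000007,benign
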