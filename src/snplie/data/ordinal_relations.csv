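better,worse
N101(2.60)K,N101(2.60)I
E121(3.29)Q,E121(3.29)A
WT,E121(3.29)A
WT,E121(3.29)Q
WT,R292(7.34)A
WT,R292(7.34)V
W269(6.48)E,W269(6.48)A
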