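,Hvar,Osijek,Pula,Split,Varazdin
Hvar,1.0,0.0097,0.0042,0.324,0.0001
Osijek,0.0097,1.0,0.1138,0.1199,0.0001
Pula,0.0042,0.1138,1.0,0.0233,0.026
Split,0.324,0.1199,0.0233,1.0,0.0001
Varazdin,0.0001,0.0001,0.026,0.0001,1.0
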