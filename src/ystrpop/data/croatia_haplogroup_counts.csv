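region,I1,I2a,I2b,J1,J2a,J2b,R1a,R1b,G1,G2a,E1b1b,Q,T,L
Hvar,3,55,0,0,4,1,11,4,0,6,12,8,0,0
Varazdin,8,18,3,1,4,3,38,9,0,0,16,0,0,0
Split,5,53,2,0,2,3,20,5,1,0,11,1,2,0
Pula,9,31,1,1,3,2,28,8,0,3,11,0,1,1
Osijek,12,45,1,1,5,2,29,7,0,1,6,1,0,0
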