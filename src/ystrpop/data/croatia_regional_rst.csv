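,Hvar,Osijek,Pula,Split,Varazdin
Hvar,0.0,0.021,0.0284,0.0009,0.0979
Osijek,0.021,0.0,0.0069,0.0063,0.0551
Pula,0.0284,0.0069,0.0,0.018,0.0166
Split,0.0009,0.0063,0.018,0.0,0.0821
Varazdin,0.0979,0.0551,0.0166,0.0821,0.0
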