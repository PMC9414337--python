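activity_score,met_rel,dex_rel
0,0,0
0.25,,2
0.5,19,14
0.75,,
1,,40
1.25,64,48
1.5,72,63
2,100,100
3,213,170
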