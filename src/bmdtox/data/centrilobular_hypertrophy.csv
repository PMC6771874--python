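dose,n,affected
0,70,0
0.1,70,0
1,70,0
50,70,7
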