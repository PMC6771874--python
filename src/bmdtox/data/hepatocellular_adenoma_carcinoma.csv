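dose,n,affected
0,70,2
0.1,70,2
1,70,1
50,70,3
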