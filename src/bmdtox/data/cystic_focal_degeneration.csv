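dose,n,affected
0,70,24
0.1,70,24
1,70,19
50,70,42
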