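N,a,b
50,0.2,0.3
100,0.2,0.3
300,0.2,0.3
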