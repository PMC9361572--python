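genome=ginseng
G2=0.0297
G1=0.2884
gamma=1.2560
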