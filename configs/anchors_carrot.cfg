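genome=carrot
alpha=0.3659
carrot-omega=0.7470
gamma=1.2560
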