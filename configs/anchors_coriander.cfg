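genome=coriander
alpha=0.3659
coriander-omega=0.7194
gamma=1.2560
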