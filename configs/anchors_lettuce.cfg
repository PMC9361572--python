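genome=lettuce
L1=0.6415
gamma=1.2560
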