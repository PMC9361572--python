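# Ks anchors of the polyploidization events in the celery genome
genome=celery
alpha=0.3659
celery-omega=0.7154
gamma=1.2560
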