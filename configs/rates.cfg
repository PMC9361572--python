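# neutral substitution rates, substitutions per site per year
apiaceae=5.2e-9
dicot=1.5e-8
use=apiaceae
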