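2
H2 at 0.74 Angstrom
H 0.0 0.0 0.0
H 0.0 0.0 0.74
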