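2
CO stretched to 1.54 Angstrom
C 0.0 0.0 0.0
O 0.0 0.0 1.54
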