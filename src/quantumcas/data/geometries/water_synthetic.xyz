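3
synthetic water fixture: r(OH)=0.9572 A, HOH=104.52 deg (standard experimental geometry)
O 0.0000000000 0.0000000000 0.1173000000
H 0.0000000000 0.7572000000 -0.4692000000
H 0.0000000000 -0.7572000000 -0.4692000000
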