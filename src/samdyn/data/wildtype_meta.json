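{
 "t": 0.0,
 "R": 2.5,
 "r": 0.9500000000001798,
 "u3_center": 0.1711791801761817,
 "n_r": 200
}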