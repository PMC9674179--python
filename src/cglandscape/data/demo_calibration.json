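{
 "lambda": 1.6105,
 "tether_k": 0.2,
 "calibration_dg": 8.038,
 "calibration_ddg": 1.944,
 "master_seed": 1
}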