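{
 "seed": 1,
 "out_dir": "demo",
 "n_subjects": 6,
 "n_perm": 100,
 "rest_timepoints": 300,
 "n_feature_subjects": 49
}
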