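{
  "strata": [
    {"name": "discovery_fh", "n_individuals": 186, "role": "case"},
    {"name": "validation_fh", "n_individuals": 858, "role": "case"},
    {"name": "sporadic", "n_individuals": 1074, "role": "case"},
    {"name": "control", "n_individuals": 1171, "role": "control"}
  ],
  "sets": [
    {"name": "familial", "members": ["discovery_fh", "validation_fh"]},
    {"name": "nonfamilial", "members": ["sporadic", "control"]}
  ]
}
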