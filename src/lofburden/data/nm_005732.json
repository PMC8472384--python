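{
  "transcript_id": "NM_005732",
  "cds_length": 3939,
  "domains": [
    {"name": "zinc_hook", "start": 635, "end": 734}
  ]
}
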