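{
  "N": 8,
  "p_at_k": {
    "P@3": 1.0,
    "P@5": 1.0
  },
  "ap": 1.0,
  "raw": {
    "p_at_k": {
      "P@3": 1.0,
      "P@5": 1.0
    },
    "ap": 1.0,
    "per_set_aps": {},
    "map": null
  }
}
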