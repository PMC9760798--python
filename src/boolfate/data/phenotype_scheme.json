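{
  "labels": ["M0", "M1", "M2a", "M2b", "M2c", "M2d"],
  "fallback": "M0",
  "conditions": {
    "M1": "STAT1 | NFKB",
    "M2a": "STAT6",
    "M2b": "AP1",
    "M2c": "STAT3",
    "M2d": "HIF1A"
  },
  "outcome_class": {
    "M0": "neutral",
    "M1": "tumor-eliminating",
    "M2a": "tumor-promoting",
    "M2b": "tumor-promoting",
    "M2c": "tumor-promoting",
    "M2d": "tumor-promoting"
  }
}
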