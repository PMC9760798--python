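{
  "n_nodes": 17,
  "n_states": 131072,
  "n_attractors": 2048,
  "n_fixed_points": 2048,
  "period_counts": {
    "1": 2048
  },
  "census_sha256": "000212e8ac96f40e4e8e5cdb1787f962330919993460bb142b6fa6c84ed4408e",
  "fatemap_attractors": 64,
  "fatemap_edges": 1088,
  "fatemap_sha256": "0b93ee40f66a1dd81d5a631d30910443171fd8801abb345c78dec80dfce66d1f"
}
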