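{
  "name": "Cs-137",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library",
  "half_life_s": 949300000.0,
  "mode": "beta",
  "alpha_lines": [],
  "beta_branches": [[0.5120, 0.946, 56], [1.1756, 0.054, 56]],
  "electron_lines": [[0.6242, 0.0789], [0.6557, 0.0141]]
}
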