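{
  "name": "I-131",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library",
  "half_life_s": 693400.0,
  "mode": "beta",
  "alpha_lines": [],
  "beta_branches": [[0.6063, 0.896, 54], [0.3338, 0.072, 54], [0.2478, 0.021, 54]],
  "electron_lines": [[0.3299, 0.0163]]
}
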