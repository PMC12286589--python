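{
  "name": "Rn-222",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library; parent only (progeny chain off by default)",
  "half_life_s": 330350.0,
  "mode": "alpha",
  "alpha_lines": [[5.4895, 0.9992]],
  "beta_branches": [],
  "electron_lines": []
}
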