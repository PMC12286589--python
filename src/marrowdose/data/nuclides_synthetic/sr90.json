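{
  "name": "Sr-90",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library; parent only (no Y-90 in-growth)",
  "half_life_s": 908800000.0,
  "mode": "beta",
  "alpha_lines": [],
  "beta_branches": [[0.5460, 1.0, 39]],
  "electron_lines": []
}
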