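{
  "name": "Th-232",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library; parent only",
  "half_life_s": 4.434e+17,
  "mode": "alpha",
  "alpha_lines": [[4.0123, 0.782], [3.9472, 0.217]],
  "beta_branches": [],
  "electron_lines": []
}
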