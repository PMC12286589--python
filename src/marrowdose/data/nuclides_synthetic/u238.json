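{
  "name": "U-238",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library; parent only",
  "half_life_s": 1.41e+17,
  "mode": "alpha",
  "alpha_lines": [[4.198, 0.79], [4.151, 0.21]],
  "beta_branches": [],
  "electron_lines": []
}
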