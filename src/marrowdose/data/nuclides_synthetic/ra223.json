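{
  "name": "Ra-223",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library; parent only (progeny chain off by default)",
  "half_life_s": 987600.0,
  "mode": "alpha",
  "alpha_lines": [[5.7162, 0.518], [5.6067, 0.252], [5.7470, 0.090], [5.5398, 0.090], [5.4332, 0.022]],
  "beta_branches": [],
  "electron_lines": []
}
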