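{
  "name": "Pu-239",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library",
  "half_life_s": 760500000000.0,
  "mode": "alpha",
  "alpha_lines": [[5.1566, 0.708], [5.1443, 0.171], [5.1055, 0.119]],
  "beta_branches": [],
  "electron_lines": []
}
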