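{
  "name": "Xe-133",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library",
  "half_life_s": 453400.0,
  "mode": "noble_gas_beta",
  "alpha_lines": [],
  "beta_branches": [[0.3461, 0.985, 55]],
  "electron_lines": [[0.0450, 0.528], [0.0750, 0.092]]
}
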