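{
  "name": "Xe-135",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library",
  "half_life_s": 32900.0,
  "mode": "noble_gas_beta",
  "alpha_lines": [],
  "beta_branches": [[0.9150, 0.960, 55], [0.5570, 0.031, 55]],
  "electron_lines": [[0.2139, 0.057]]
}
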