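{
  "name": "Kr-85",
  "note": "synthetic approximate decay data for fixtures; not an evaluated library",
  "half_life_s": 339400000.0,
  "mode": "noble_gas_beta",
  "alpha_lines": [],
  "beta_branches": [[0.6874, 0.9957, 37], [0.1734, 0.0043, 37]],
  "electron_lines": []
}
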