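{
 "description": "Posterior-mean demographic rates (log scale) of the two-species Fagus/others system fitted to the German national forest inventory, with stage-threshold constants.",
 "species": ["fagus", "others"],
 "log_params": {
  "r": [2.349, 4.825],
  "l": [4.018, 5.398],
  "c_J": [-11.56, -9.77],
  "s": [-8.908, -1.211],
  "g": [-5.519, -3.591],
  "c_A": [-9.421, -6.811],
  "h": [-2.683, -2.843],
  "b": [-4.779, -3.599],
  "c_B": [-7.287, -6.691]
 },
 "constants": {
  "beta_uA": 0.025446900494077323,
  "beta_mA": [0.01586, 0.01611],
  "dbh_JA_cm": 10.0,
  "dbh_AB_cm": 18.0
 }
}
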