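{
 "description": "Reference mean stage abundances (J, A in counts/ha; B, BA in m2/ha) of the fitted two-species system: observed initial state, fitted initial model state, and extrapolated equilibrium, with cross-plot standard deviations of the observed initial state and posterior-mean dispersion levels.",
 "species": ["fagus", "others"],
 "initial_data": {"J": [1623.4, 4467.9], "A": [72.964, 245.78], "B": [4.0505, 14.872], "BA": [5.1049, 18.395]},
 "initial_data_sd": {"J": [5361.1, 13412.0], "A": [209.83, 453.27], "B": [7.5868, 15.39], "BA": [8.5159, 16.071]},
 "initial_model": {"J": [1649.3, 4492.1], "A": [75.714, 247.92], "B": [4.1454, 15.016], "BA": [5.3459, 19.01]},
 "equilibrium": {"J": [5265.2, 4304.5], "A": [262.55, 92.517], "B": [25.971, 7.5556], "BA": [30.133, 9.0462]},
 "equilibrium_total_BA": 39.179,
 "phi": {
  "J|fagus|initial": 13810.0, "J|others|initial": 25120.0,
  "J|fagus|survey2": 0.2561, "J|others|survey2": 0.2334,
  "J|fagus|survey3": 0.3029, "J|others|survey3": 0.2045,
  "A|fagus|initial": 7896.0, "A|others|initial": 8034.0,
  "A|fagus|later": 2.047, "A|others|later": 1.472,
  "B|fagus|initial": 9504.0, "B|others|initial": 16860.0,
  "B|fagus|later": 2.399, "B|others|later": 2.745
 }
}
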