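{
  "params": {
    "tau_ET": 2722.574675217697,
    "tau_IS": 1384.9611900713664,
    "alpha_pot": 0.3797948504696911,
    "beta_pot": 14.36896744289511,
    "alpha_dep": 0.06842862747971144,
    "beta_dep": 693.0171944527445,
    "k_pot": 7.7413270251143445,
    "k_dep": 1.0215020673800834,
    "W_max": 6.0
  },
  "note": "reference configuration for warm-starting the network-rule calibration; obtained by an extended exploratory search against the synthetic calibration target set and Nelder-Mead refinement (see analysis/03_calibrate_network_rule.py)"
}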