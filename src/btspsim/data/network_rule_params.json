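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
    "W_max": 6.0,
    "lambda_ET": 0.025,
    "lambda_IS": 5.134574247103963,
    "plateau_duration_ref": 0.3
  },
  "loss": 6.629947371568657,
  "provenance": "bounded stochastic chain-search against the synthetic calibration target set with Nelder-Mead refinement; regenerate with analysis/03_calibrate_network_rule.py"
}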