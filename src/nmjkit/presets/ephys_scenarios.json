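{
  "_comment": [
    "Per age x genotype generator presets for synthetic intracellular NMJ recordings.",
    "Entries with printed=true carry published group means (corrected to -70 mV);",
    "entries with printed=false are interpolated/assumed values chosen to follow the",
    "reported age trajectories and are study-design assumptions, not measurements.",
    "The 16-week SOD1 entry encodes the reported relative effects instead of absolute",
    "means: the builder derives epp_mean from qc_reduction_vs_wt by inverting the",
    "non-linear-summation (Martin) formula, and mepp_rate from rate_reduction_vs_wt.",
    "'sym' denotes the early-symptomatic stage (18-22 weeks, age-matched WT = 20 weeks)."
  ],
  "defaults": {
    "mepp_cv": 0.30,
    "epp_cv": 0.12,
    "epp_within_cv": 0.05,
    "rise_time": 0.8,
    "decay_tau": 3.0,
    "rmp_mean": -72.0,
    "rmp_drift_sd": 1.0,
    "noise_sd": 0.1,
    "release_fraction": 0.12,
    "replenish_rate": 0.219,
    "n_nmjs": 50
  },
  "WT": {
    "2":   {"mepp_mean": 1.48, "mepp_printed": true,  "mepp_rate": 0.8, "epp_mean": 12.0, "epp_printed": false},
    "4":   {"mepp_mean": 1.35, "mepp_printed": false, "mepp_rate": 1.2, "epp_mean": 18.0, "epp_printed": false},
    "8":   {"mepp_mean": 1.06, "mepp_printed": true,  "mepp_rate": 1.6, "epp_mean": 24.0, "epp_printed": false},
    "12":  {"mepp_mean": 1.20, "mepp_printed": false, "mepp_rate": 2.0, "epp_mean": 30.0, "epp_printed": false},
    "16":  {"mepp_mean": 1.20, "mepp_printed": false, "mepp_rate": 2.0, "epp_mean": 33.0, "epp_printed": false},
    "sym": {"mepp_mean": 1.19, "mepp_printed": true,  "mepp_rate": 2.0, "epp_mean": 34.3, "epp_printed": true}
  },
  "SOD1": {
    "2":   {"mepp_mean": 1.55, "mepp_printed": false, "mepp_rate": 0.8, "epp_mean": 12.0, "epp_printed": false},
    "4":   {"mepp_mean": 1.45, "mepp_printed": false, "mepp_rate": 1.2, "epp_mean": 18.0, "epp_printed": false},
    "8":   {"mepp_mean": 1.30, "mepp_printed": true,  "mepp_rate": 1.6, "epp_mean": 24.0, "epp_printed": false},
    "12":  {"mepp_mean": 1.20, "mepp_printed": false, "mepp_rate": 2.0, "epp_mean": 28.0, "epp_printed": false,
            "rise_time": 0.6, "replenish_rate": 0.0607},
    "16":  {"mepp_mean": 1.20, "mepp_printed": false,
            "qc_reduction_vs_wt": 0.277, "rate_reduction_vs_wt": 0.437,
            "reduction_printed": true, "replenish_rate": 0.0607},
    "sym": {"mepp_mean": 0.94, "mepp_printed": true,  "mepp_rate": 2.0, "epp_mean": 30.6, "epp_printed": true,
            "replenish_rate": 0.0607}
  },
  "special": {
    "depolarized_fiber": {
      "_comment": "Unhealthy impalement used to exercise the RMP > -50 mV rejection rule.",
      "base": ["WT", "12"],
      "rmp_mean": -52.0,
      "rmp_drift_sd": 6.0,
      "bound_rmp": false
    }
  }
}
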