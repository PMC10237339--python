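{
  "_comment": [
    "Per age x genotype presets for synthetic en-face AChR micrographs.",
    "printed=true values follow the published trajectories: the wildtype",
    "reduced-intensity (dim) area fraction plateaus near 0.40 from 12 weeks,",
    "while the hSOD1-G93A fraction rises progressively to 0.60 at the early",
    "symptomatic stage; >50%-floccular NMJs never occur in wildtype and reach",
    ">20% incidence in symptomatic hSOD1-G93A; ~10% of NMJs carry small dim",
    "extrajunctional clusters at all ages in both genotypes.  Other values",
    "are generator design choices (see docs/methods.md).",
    "Intensities are arbitrary units on the 8-bit gray scale (no absolute",
    "fluorescence calibration exists); 'sym' = 18-22 weeks."
  ],
  "defaults": {
    "image_size": 512,
    "pixel_size": 0.16,
    "endplate_scale": 32.0,
    "ribbon_width": 2.5,
    "n_branches": 5,
    "bright_intensity": 185.0,
    "bright_spread": 15.0,
    "dim_intensity": 91.0,
    "dim_spread": 59.0,
    "background_level": 15.0,
    "noise_sd": 4.0,
    "floccular_fraction_small": 0.25,
    "floccular_fraction_large": 0.70,
    "satellite_intensity_lo": 0.40,
    "satellite_intensity_hi": 0.60
  },
  "WT": {
    "4":   {"dim_fraction": 0.25, "dim_printed": false, "p_floccular_small": 0.04, "p_floccular_large": 0.0, "p_extrajunctional": 0.10},
    "8":   {"dim_fraction": 0.30, "dim_printed": false, "p_floccular_small": 0.04, "p_floccular_large": 0.0, "p_extrajunctional": 0.10},
    "12":  {"dim_fraction": 0.40, "dim_printed": true,  "p_floccular_small": 0.04, "p_floccular_large": 0.0, "p_extrajunctional": 0.10},
    "16":  {"dim_fraction": 0.40, "dim_printed": true,  "p_floccular_small": 0.04, "p_floccular_large": 0.0, "p_extrajunctional": 0.10},
    "sym": {"dim_fraction": 0.40, "dim_printed": true,  "p_floccular_small": 0.04, "p_floccular_large": 0.0, "p_extrajunctional": 0.10}
  },
  "SOD1": {
    "4":   {"dim_fraction": 0.25, "dim_printed": false, "p_floccular_small": 0.04, "p_floccular_large": 0.0,  "p_extrajunctional": 0.10},
    "8":   {"dim_fraction": 0.30, "dim_printed": false, "p_floccular_small": 0.05, "p_floccular_large": 0.0,  "p_extrajunctional": 0.10},
    "12":  {"dim_fraction": 0.42, "dim_printed": false, "p_floccular_small": 0.06, "p_floccular_large": 0.02, "p_extrajunctional": 0.10},
    "16":  {"dim_fraction": 0.50, "dim_printed": true,  "p_floccular_small": 0.15, "p_floccular_large": 0.08, "p_extrajunctional": 0.10},
    "sym": {"dim_fraction": 0.60, "dim_printed": true,  "p_floccular_small": 0.20, "p_floccular_large": 0.22, "p_extrajunctional": 0.10}
  }
}
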