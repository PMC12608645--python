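{
  "name": "glucose_depletion",
  "seed": 0,
  "grid": {
    "extent_um": 3000.0,
    "voxel_um": 20.0
  },
  "species": {
    "oxygen": {
      "name": "oxygen",
      "initial_mM": 0.0494,
      "boundary_kind": "dirichlet",
      "boundary_value_mM": 0.0494
    },
    "glucose": {
      "name": "glucose",
      "initial_mM": 6.0,
      "boundary_kind": "dirichlet",
      "boundary_value_mM": 6.0
    },
    "lactate": {
      "name": "lactate",
      "initial_mM": 0.1,
      "boundary_kind": "dirichlet",
      "boundary_value_mM": 0.1
    },
    "proton": {
      "name": "proton",
      "initial_mM": 3.981071705534969e-05,
      "boundary_kind": "dirichlet",
      "boundary_value_mM": 3.981071705534969e-05
    }
  },
  "cells": {
    "n_initial": 440,
    "disc_radius_um": 420.0,
    "volume_um3": 2494.0,
    "g1_h": 5.0,
    "s_h": 8.0,
    "g2_h": 4.0,
    "m_h": 1.0,
    "density_threshold": 0.55,
    "atp_checkpoint_mM": 0.8,
    "hypoxia_floor_mmHg": 15.0,
    "o2_reference_mmHg": 38.0,
    "neighborhood_radius_um": 25.0,
    "atp_death_mM": 0.3,
    "death_persistence_h": 3.0,
    "death_p_max": 0.2,
    "swell_factor": 1.5,
    "swell_h": 6.0,
    "shrink_h": 24.0,
    "debris_volume_frac": 0.1,
    "debris_clear_h": 24.0,
    "lysis_nominal_o2_mM": 0.05,
    "gamma_init": 1.0,
    "gamma_sigma": 0.05,
    "gamma_min": 0.5,
    "gamma_max": 2.0,
    "repulsion": 10.0,
    "adhesion": 0.5,
    "adhesion_scale": 1.25
  },
  "schedule": {
    "dt_diffusion_s": 0.6,
    "dt_metabolism_s": 1.2,
    "dt_mechanics_s": 6.0,
    "dt_phenotype_s": 360.0,
    "t_end_h": 300.0
  },
  "perturbations": [
    {
      "kind": "field_clamp",
      "species": "glucose",
      "t_start_h": 0.0,
      "t_end_h": 60.0,
      "value_mM": 6.0,
      "high_mM": null,
      "low_mM": null,
      "period_h": null
    },
    {
      "kind": "field_clamp",
      "species": "glucose",
      "t_start_h": 60.0,
      "t_end_h": Infinity,
      "value_mM": 0.01,
      "high_mM": null,
      "low_mM": null,
      "period_h": null
    }
  ],
  "outputs": {
    "snapshot_every_h": 1.0,
    "out_dir": null,
    "save_fields": false,
    "ldh_range": [
      0.0,
      8.0
    ],
    "pdh_range": [
      0.0,
      1.5
    ],
    "landscape_bins": 60,
    "radial_bin_um": 20.0
  },
  "noise_sigma": null,
  "param_table": null
}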