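# Default trait system for the synthetic horse study.
#
# Gait measurement means/SDs and velocities follow the descriptive scale of
# accelerometric gait testing of young jumping horses (working/medium trot
# and canter, walk).  Heritabilities and repeatabilities echo published
# magnitudes for these measurements; correlation structure is generated
# from factor loadings (g_load genetic, e_load environmental) on three
# latent factors: F1 vertical motion (high dorsoventral displacement, low
# stride frequency), F2 activity (longitudinal/lateral accelerations),
# F3 walk-specific/regularity.  Correlation matrices are L L' + diag
# uniqueness, hence positive semi-definite by construction.
#
# All loadings refer to standardized (unit phenotypic variance) traits.

factors: [vertical, activity, walkish]

gaits:
  trot:
    code: T
    velocity:
      working: [3.57, 0.43]
      medium: [4.35, 0.43]
    measurements:
      SF:  {mean_working: 1.37,  mean_medium: 1.46,  sd: 0.075, beta_v: 0.30,
            h2: 0.46, rep: 0.66, g_load: [-0.60, 0.35, 0.00], e_load: [-0.36, 0.21, 0.00]}
      R:   {mean_working: 348.4, mean_medium: 312.0, sd: 41.0,  beta_v: -0.15,
            h2: 0.05, rep: 0.25, g_load: [0.10, -0.10, 0.30],  e_load: [0.06, -0.06, 0.18]}
      S:   {mean_working: 5.50,  mean_medium: 5.45,  sd: 0.20,  beta_v: -0.10,
            h2: 0.04, rep: 0.08, g_load: [0.05, 0.00, 0.30],   e_load: [0.03, 0.00, 0.18]}
      DVD: {mean_working: 10.75, mean_medium: 10.38, sd: 1.87,  beta_v: -0.15,
            h2: 0.47, rep: 0.63, g_load: [0.70, 0.00, 0.15],   e_load: [0.42, 0.00, 0.09]}
      DVA: {mean_working: 14.73, mean_medium: 19.45, sd: 3.25,  beta_v: 0.30,
            h2: 0.33, rep: 0.70, g_load: [0.55, 0.15, 0.10],   e_load: [0.33, 0.09, 0.06]}
      LGA: {mean_working: 2.14,  mean_medium: 2.36,  sd: 0.32,  beta_v: 0.30,
            h2: 0.36, rep: 0.79, g_load: [0.05, 0.70, 0.00],   e_load: [0.03, 0.42, 0.00]}
      LTA: {mean_working: 0.98,  mean_medium: 1.34,  sd: 0.34,  beta_v: 0.30,
            h2: 0.17, rep: 0.65, g_load: [0.10, 0.55, 0.25],   e_load: [0.06, 0.33, 0.15]}
  canter:
    code: C
    velocity:
      working: [5.20, 0.58]
      medium: [6.22, 0.70]
    measurements:
      SF:  {mean_working: 1.68,  mean_medium: 1.73,  sd: 0.075, beta_v: 0.30,
            h2: 0.44, rep: 0.65, g_load: [-0.60, 0.35, 0.00],  e_load: [-0.36, 0.21, 0.00]}
      R:   {mean_working: 127.2, mean_medium: 113.3, sd: 23.5,  beta_v: -0.15,
            h2: 0.10, rep: 0.23, g_load: [0.10, -0.10, 0.30],  e_load: [0.06, -0.06, 0.18]}
      DVD: {mean_working: 20.50, mean_medium: 21.36, sd: 2.30,  beta_v: 0.20,
            h2: 0.51, rep: 0.58, g_load: [0.70, 0.00, 0.15],   e_load: [0.42, 0.00, 0.09]}
      DVA: {mean_working: 2.70,  mean_medium: 2.93,  sd: 0.175, beta_v: 0.30,
            h2: 0.30, rep: 0.59, g_load: [0.55, 0.15, 0.10],   e_load: [0.33, 0.09, 0.06]}
      LGA: {mean_working: 2.46,  mean_medium: 2.96,  sd: 0.44,  beta_v: 0.30,
            h2: 0.19, rep: 0.66, g_load: [0.05, 0.70, 0.00],   e_load: [0.03, 0.42, 0.00]}
      LTA: {mean_working: 1.68,  mean_medium: 1.95,  sd: 0.32,  beta_v: 0.30,
            h2: 0.07, rep: 0.50, g_load: [0.10, 0.55, 0.25],   e_load: [0.06, 0.33, 0.15]}
  walk:
    code: W
    velocity:
      walk: [1.77, 0.20]
    measurements:
      SF:  {mean: 0.91,  sd: 0.06, beta_v: 0.40,
            h2: 0.15, g_load: [-0.30, 0.55, 0.00], e_load: [-0.18, 0.33, 0.00]}
      R:   {mean: 178.3, sd: 47.3, beta_v: 0.15,
            h2: 0.05, g_load: [0.30, 0.00, 0.30],  e_load: [0.18, 0.00, 0.18]}
      S:   {mean: 5.30,  sd: 0.26, beta_v: 0.15,
            h2: 0.04, g_load: [0.25, 0.00, 0.35],  e_load: [0.15, 0.00, 0.21]}
      DVD: {mean: 3.97,  sd: 1.46, beta_v: 0.35,
            h2: 0.16, g_load: [0.55, 0.00, 0.35],  e_load: [0.33, 0.00, 0.21]}
      DVA: {mean: -0.22, sd: 0.46, beta_v: 0.35,
            h2: 0.12, g_load: [0.45, 0.00, 0.40],  e_load: [0.27, 0.00, 0.24]}
      LGA: {mean: 0.96,  sd: 0.40, beta_v: 0.30,
            h2: 0.10, g_load: [0.00, 0.60, 0.20],  e_load: [0.00, 0.36, 0.12]}
      LTA: {mean: 0.24,  sd: 0.35, beta_v: 0.30,
            h2: 0.08, g_load: [0.10, 0.40, 0.30],  e_load: [0.06, 0.24, 0.18]}

height:
  mean: 166.75
  sd: 4.16
  h2: 0.33
  g_load: [0.40, -0.25, 0.10]

competition:
  h2: 0.30
  repeatability: 0.52
  g_load: [0.00, -0.20, 0.00]

judge:
  mean: 13.5
  sd: 1.8
  h2_intrinsic: 0.25
  g_load: [0.05, -0.10, 0.00]
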