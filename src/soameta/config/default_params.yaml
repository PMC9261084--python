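# Calibrated generative defaults for the synthetic cohort.
# Produced by scripts/calibrate.py: staged grid search matching the
# published group statistics (d' = 1.8 / 0.76, c = -0.43 / -0.73,
# gamma = 0.26 / 0.00) and a mid-band slope-classifier accuracy, under
# the study design (30 participants/group, 240 trials, missingness
# 1.9% / 8.4%).
control:
  delta_mean:
    temporal:
    - 0.992
    - 1.9839
    - 2.9759
    spatial:
    - 0.992
    - 1.9839
    - 2.9759
  delta_sd: 0.65
  kappa_mean: 1.351272292272255
  kappa_sd: 0.5
  sigma_meta_mean: 1.1
  sigma_meta_sd: 0.4
  confidence_gain: 1.0
  confidence_offset: 0.0
  missing_rate: 0.019
  n_participants: 30
psychosis:
  delta_mean:
    temporal:
    - 0.3542
    - 0.7083
    - 1.0625
    spatial:
    - 0.3542
    - 0.7083
    - 1.0625
  delta_sd: 0.65
  kappa_mean: 1.144579096997605
  kappa_sd: 0.5
  sigma_meta_mean: 3.5
  sigma_meta_sd: 1.2
  confidence_gain: 1.0
  confidence_offset: 0.0
  missing_rate: 0.084
  n_participants: 30
panss_positive_gamma_coupling: -0.47
clinical_marginals:
  panss_positive:
  - 15.1
  - 3.2
  panss_negative:
  - 15.2
  - 5.2
  panss_general:
  - 32.5
  - 7.0
  spqb_cogper:
  - 2.5
  - 1.8
  spqb_inter:
  - 2.8
  - 2.0
  spqb_disorg:
  - 1.7
  - 1.5
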