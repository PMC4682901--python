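# Default synthetic-cohort configuration.
#
# These values define the reference study conditions for every simulation in
# the package: a surgical breast-cancer cohort of 2,250 patients dominated by
# HR+/HER2- disease, diameters on the cm scale capped at the 10 cm inclusion
# limit, triple-negative tumors the most spherical (Beta ratio mass near 1),
# node positivity around 40% rising with SED, a low monthly hazard of distant
# metastasis with SED-tertile and subtype shifts, and a 41-sample FPKM matrix
# with planted SED-correlated genes.  Effect sizes are model assumptions
# chosen for qualitative realism, not measured values.

n_patients: 2250
subtype_proportions:
  HR+/HER2-: 0.58
  HR+/HER2+: 0.07
  HR-/HER2+: 0.10
  HR-/HER2-: 0.25
# largest diameter a ~ lognormal(median_cm, log_sd), truncated to (0, 10]
diameter_scale:
  HR+/HER2-: [2.1, 0.45]
  HR+/HER2+: [2.4, 0.45]
  HR-/HER2+: [2.7, 0.45]
  HR-/HER2-: [2.5, 0.45]
# diameter ratios b/a and c/b ~ Beta(alpha, beta); mass near 1 => spherical
eccentricity_params:
  HR+/HER2-: [4.0, 4.0]
  HR+/HER2+: [4.0, 4.0]
  HR-/HER2+: [5.0, 3.0]
  HR-/HER2-: [8.0, 2.0]
max_diameter_cm: 10.0
# lymph-node positivity: logit p = intercept + beta_sed*SED + beta_size*a
node_intercept: -2.0
node_beta_sed: 1.5
node_beta_size: 0.2
# DMFS hazard (events/month), exponential; log-hazard shifts below
baseline_hazard_per_month: 0.0015
hazard_coef_sed_group: {Low: 0.0, Middle: 0.4, High: 0.8}
# subtype shifts kept modest and equal within HR- so the SED hazard signal
# is identifiable instead of cancelled by subtype confounding
hazard_coef_subtype:
  HR+/HER2-: 0.0
  HR+/HER2+: 0.2
  HR-/HER2+: 0.3
  HR-/HER2-: 0.3
censoring_rate_per_month: 0.006
follow_up_months: 150.0
grade_probs:
  HR+/HER2-: [0.25, 0.50, 0.25]
  HR+/HER2+: [0.10, 0.45, 0.45]
  HR-/HER2+: [0.05, 0.35, 0.60]
  HR-/HER2-: [0.05, 0.25, 0.70]
grade_missing_rate: 0.02
# expression block
n_expression_samples: 41
n_genes: 2000
planted_correlations: [-0.54, -0.52, -0.51, -0.50, -0.48, -0.47, -0.46, -0.45,
                       -0.44, -0.43, -0.42, -0.41, 0.41, 0.43, 0.45, 0.47,
                       0.50, 0.52, 0.54, 0.60]
planted_mean_range: [30.0, 2000.0]
planted_log_sd_range: [0.9, 1.4]
null_mean_median: 60.0
null_mean_log_sd: 1.8
null_log_sd_range: [0.5, 1.6]
seed: null
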