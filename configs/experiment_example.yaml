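# Example experiment configuration for `narrsim run`.
# Scaled down (one outcome, three budgets) so it finishes in seconds;
# widen outcomes/budgets for the full grid.
generator:
  n_records: 8000
  seed: 11
  prevalence:
    drive_by: 0.092
    legal_intervention: 0.059
    nonfatal_others_shot: 0.152
    injured_at_home: 0.248
  race_marginal: {aian_nh: 0.011, api_nh: 0.011, black_nh: 0.605, hispanic: 0.145, white_nh: 0.216}
  sex_marginal: {female: 0.157, male: 0.843}
  length_params:
    black_nh:  {median_le: 77, iqr_le: 87,  median_cme: 85,  iqr_cme: 71}
    hispanic:  {median_le: 67, iqr_le: 107, median_cme: 87,  iqr_cme: 101}
    white_nh:  {median_le: 99, iqr_le: 140, median_cme: 103, iqr_cme: 104}
    aian_nh:   {median_le: 80, iqr_le: 100, median_cme: 89,  iqr_cme: 83}
    api_nh:    {median_le: 80, iqr_le: 100, median_cme: 89,  iqr_cme: 83}
  circumstances_known_rate:
    black_nh: 0.710
    hispanic: 0.837
    white_nh: 0.832
    aian_nh: 0.758
    api_nh: 0.758

outcomes: [legal_intervention]
variants: [base, language_replacement]
budgets: [200, 500, 1000]
oversample:
  base_budget: 1000
  target_fractions: [0.10, 0.20]
classifier:
  backend: linear_baseline
  seed: 0
test_fraction: 0.30
subgroup_keys: [race_ethnicity, sex]
output_dir: results/example_run
root_seed: 11
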