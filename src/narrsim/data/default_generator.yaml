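# Default synthetic-cohort calibration.
#
# Values follow published descriptive statistics for firearm homicides in
# the US National Violent Death Reporting System, 2015-2020: outcome
# prevalences 5.9% (legal intervention), 9.2% (drive-by), 15.2% (others
# nonfatally shot), 24.8% (injured at home); subgroup composition and
# narrative-length medians/IQR widths by race/ethnicity; circumstances-known
# rates of 71% for Black non-Hispanic decedents versus ~83-84% for Hispanic
# and White non-Hispanic decedents.  AIAN/API subgroups are not broken out
# in the published narrative tables and fall back to the overall row.
n_records: 20000
seed: 20150

prevalence:
  drive_by: 0.092
  legal_intervention: 0.059
  nonfatal_others_shot: 0.152
  injured_at_home: 0.248

# Outer product of these marginals (normalized) gives the subgroup mix.
race_marginal:
  aian_nh: 0.011
  api_nh: 0.011
  black_nh: 0.605
  hispanic: 0.145
  white_nh: 0.216
sex_marginal:
  female: 0.157
  male: 0.843

# Median and IQR width in whitespace words, per narrative source.
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

signal_strength: 0.9
leak_rate: 0.05
abbrev_rate: 0.3
context_rate: 0.7
bias_knobs: {}
uninformative_cap: 15
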