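# Full pipeline run on a simulated cohort.
# `adtrends run-all --config examples/run.yaml out/`
simulate: true

study:
  study_start_year: 1995
  study_end_year: 2011
  min_age_years: 14
  lookback_years: 3
  gap_months: 4
  duration_last_start_year: 2009

simulation:
  n_patients: 5000
  seed: 42
  # per-year parameters may be given sparsely; values are clamped outside
  # the covered years (defaults interpolate full 1992-2011 profiles)

strata: [none, sex, age_band, drug_class]
sensitivity: [exclude_low_dose_ami, depression_subgroup]
max_joinpoints: 4
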