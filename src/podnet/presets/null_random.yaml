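# Single undifferentiated cluster: within-period grouping is exchangeable, so
# association is random by construction — the type-I-error scenario for the
# permutation test.
cluster_sizes: [20]
within_attendance: 0.6
between_propensity: 0.0
fusion_probability: 0.0
max_subgroups: 4
n_years: 4
survey_days_per_year: 12
identification_probability: 1.0
detection_probability: 1.0
transients_per_year: 0.0
n_calves: 0
diel_schedule:
  0:
    "morning|core": 0.6
trawler_propensity:
  0: [0.0, 0.0]
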