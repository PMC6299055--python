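# Two permanent cliques with full detection and identification: between-clique
# association is exactly zero and within-clique half-weight indices are 1.
cluster_sizes: [5, 5]
within_attendance: 1.0
between_propensity: 0.0
fusion_probability: 1.0
n_years: 3
survey_days_per_year: 10
identification_probability: 1.0
detection_probability: 1.0
transients_per_year: 0.0
n_calves: 0
diel_schedule:
  0:
    "morning|core": 0.5
  1:
    "afternoon|core": 0.5
trawler_propensity:
  0: [0.2, 0.0]
  1: [0.0, 0.0]
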