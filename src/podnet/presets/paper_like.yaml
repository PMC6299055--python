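# Three-cluster resident society: ~38 marked residents surveyed over 9 years,
# strict diel partitioning of the core area between clusters 0 and 1, and
# cluster-0-dominated trawler use.  These are the package defaults spelled out.
cluster_sizes: [19, 13, 6]
within_attendance: 0.75
between_propensity: 0.01
fusion_probability: 0.35
max_subgroups: 4
n_years: 9
survey_days_per_year: 8
identification_probability: 0.9
detection_probability: 0.9
female_fraction: 0.5
unknown_sex_fraction: 0.35
transients_per_year: 2.0
n_calves: 2
start_year: 2003
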