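# podnet

Social-network analysis for photo-identification encounter data from small,
individually recognisable animal populations — built for coastal dolphin
studies, applicable to any "gambit of the group" dataset in which all members
of an observed group are taken to be associated.

Given encounter records (groups, their identified members, and a registry of
individuals), the package answers the questions a social-structure study
asks:

- **Do individuals have preferred or avoided companions?** Half-weight
  association indices (HWI, and a gregariousness-corrected variant HWIG),
  tested with the Manly–Bejder within-period permutation procedure: 2×2
  checkerboard swaps that preserve every group size and every individual's
  sighting record, so only the *pairing* of individuals is randomised.
- **How persistent are associations?** Standardised lagged association rates
  g'(τ) with temporal-jackknife SEs and a within-period permutation null,
  plus maximum-quasi-likelihood fits of the four classic social-dynamics
  models (constant companions, casual acquaintances, their sum, and two decay
  timescales) ranked by QAIC.
- **Is the population structured into social units?** Average-linkage
  dendrograms validated by the cophenetic correlation coefficient, weighted
  Newman modularity Q (plain and gregariousness-corrected), eigenvector
  community detection, and the modularity-optimal dendrogram cut.
- **How differentiated is the society, and is the sampled network faithful?**
  A beta-binomial maximum-likelihood estimate of social differentiation S
  (the CV of true dyadic association probabilities) and of the correlation r
  between true and estimated indices, with bootstrap SEs.
- **Who uses the area when, and who interacts with fisheries?** Node-level
  network metrics, Mantel class tests (clusters, sexes), group sex
  composition, diel-partitioning contingency tests (Fisher's exact), and
  trawler-interaction summaries per individual, cluster, and gear.

Because real sighting datasets of this kind are rarely public, the package
ships a fission–fusion society simulator with known ground truth (cluster
labels, true association probabilities, true S) so that every stage of the
pipeline is validated end-to-end: cluster recovery by adjusted Rand index,
permutation-test type-I calibration, S recovery, and model-selection hit
rates.

## Worked example

```python
import dataclasses
from podnet import (load_preset, simulate, apply_restrictions,
                    build_period_matrices, dyad_counts, hwi, permutation_test,
                    average_linkage, eigenvector_communities,
                    social_differentiation)

cfg = dataclasses.replace(load_preset("paper_like"), seed=7)
table, truth = simulate(cfg)                       # ~38 residents, 9 years
restricted, retained = apply_restrictions(table)   # >=4 sightings in >=2 years
pm = build_period_matrices(restricted, period_length_days=1)
counts = dyad_counts(pm)
m = hwi(counts)

perm = permutation_test(pm, n_perm=2000, flips_between_saves=100, seed=7)
print(f"observed SD = {perm.observed['sd']:.3f}, "
      f"random SD = {perm.null_distribution['sd'].mean():.3f}, "
      f"p = {perm.p_value['sd']:.4f}")

clusters = eigenvector_communities(m)
dend = average_linkage(m)
print(f"clusters: {sorted(clusters.cluster_sizes().values())}, "
      f"Q = {clusters.modularity_q:.3f}, CCC = {dend.ccc:.3f}")

diff = social_differentiation(counts, n_bootstrap=300, seed=7)
print(f"S = {diff.s:.3f} +/- {diff.s_se:.3f}, r = {diff.r:.3f} +/- {diff.r_se:.3f}")
```

Output:

```
observed SD = 0.220, random SD = 0.168, p = 0.0000
clusters: [6, 13, 19], Q = 0.463, CCC = 0.964
S = 1.391 +/- 0.056, r = 0.934 +/- 0.003
```

Reading it: the SD of the dyadic indices is far above its permutation null
(p < 1/2000), so companionship is non-random; community detection recovers
the three planted clusters (19, 13 and 6 animals) with modularity well above
the 0.3 rule of thumb, and the dendrogram is a faithful representation
(CCC ≈ 0.96); S ≈ 1.4 indicates a well-differentiated society and r ≈ 0.93
says the sampled matrix tracks the true one closely.

## Command line

Every stage is also a CLI subcommand over the three-CSV input contract
(`encounters.csv`, `memberships.csv`, `individuals.csv`):

```
podnet simulate --preset paper_like --seed 7 --out sim/
podnet validate sim/encounters.csv sim/memberships.csv sim/individuals.csv
podnet restrict sim/encounters.csv sim/memberships.csv sim/individuals.csv
podnet permtest ... --n-perm 20000
podnet cluster ... --method eigenvector
podnet run config.yaml        # the full pipeline from a YAML config
```

`podnet run` writes every stage artefact (matrices, permutation JSON, SLAR
curve and model fits, Newick dendrogram, cluster labels, GraphML networks,
diel and fishery tables, plots) plus a single `summary.json`.

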