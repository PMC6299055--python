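# Methods

This note documents the statistical machinery implemented in `podnet`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-society validation does and does not demonstrate.

## Data model and restriction rules

Input data follow the "gambit of the group" convention of small-cetacean
photo-identification studies: all members of an observed group are assumed to
be associated, and an *encounter* (one group, one date) together with its
identified members is the unit of observation. The sampling period is the
calendar day by default; multi-day periods tile the calendar from the first
observation date (the anchoring is a package convention — nothing in the data
dictates it).

Analyses are restricted to a resident subset: dependent calves are removed
(their sightings are not independent of the mother's), and an individual is
retained only if encountered on ≥ 4 occasions **and** in ≥ 2 distinct calendar
years. The two-year requirement removes animals seen many times but only
within a single season — visitors or transients whose inclusion would dilute
the network. Same-day encounters whose *retained* membership sets are
identical are treated as duplicate records of one group and deduplicated
(keeping the earliest); same-day encounters with different membership are
genuinely different groups and kept. Because deduplication can change
sighting counts, the filter is iterated to a fixed point, which makes it
idempotent. Individuals never retained are dropped from the period matrices
entirely rather than carried as all-zero columns; this affects the effective
N in null rates and is therefore a deliberate, documented choice.

## Association indices

The half-weight index for a dyad (a, b) is

    HWI = x / (x + y_ab + (y_a + y_b)/2)

with x the periods jointly associated, y_ab the periods both identified but
apart, and y_a, y_b the periods only one was identified. It estimates the
probability that one member of the dyad is associated with the other in a
period in which the focal animal is identified, and is the least biased
standard index when not every group member can be photographed. Dyads whose
denominator is zero (neither animal ever identified) are reported as 0 with a
warning.

The gregariousness-corrected index divides each dyad's HWI by its
strength-based expectation r_a·r_b/T (row sums over total ordered
association), giving the observed/expected ratio HWI·T/(r_a·r_b). Because
that ratio is dimensionless (it straddles 1), the default `scale="index"`
additionally multiplies by the mean index so corrected values remain on the
association-index scale; on a matrix with all indices equal to h every
corrected value is then h·N/(N−1). The raw ratio is available via
`scale="ratio"`. Downstream modularity is invariant to the uniform rescaling,
so cluster delineation does not depend on this choice.

## Permutation test for preferred/avoided companionship

The null model fixes each period's group-by-individual margins (group sizes
and each individual's number of memberships within the period) and randomises
the incidence matrix by a Markov chain of 2×2 checkerboard swaps confined to
single periods — individuals are never moved across periods, so the test is
robust to demographic turnover and variable effort between periods. A swap is
proposed by sampling a period (probability proportional to matrix size), two
of its groups, and one column from each discordant set; because the
discordant-set sizes are invariant under the swap the proposal is symmetric
and the chain's stationary distribution is uniform over matrices with the
observed margins.

Defaults: 20,000 saved permutations, 100 swaps between saves, 1,000-swap
burn-in (the save spacing and burn-in are mixing choices, configurable). The
half-weight denominator depends only on per-period identification margins,
which the chain preserves, so only the joint counts are updated — the update
is incremental and exact (verified against full recomputation in tests). The
test statistics are the SD and CV of the dyadic indices; p is the one-sided
(greater) proportion of saved permutations at or above the observed value,
matching the directional hypothesis that real societies show *more* dyadic
variation than chance; two-sided values are also reported. A p-trace (p after
each save) is kept for convergence diagnostics. Calibration: on societies
with exchangeable within-period grouping the empirical rejection rate at
α = 0.05 sits inside the binomial 95% band (60 replicates × 300 permutations
in the test suite).

## Standardised lagged association rates

For ordered period pairs (j, k), the estimator accumulates
numerator Σ a_j(A,B)·a_k(A,B) and denominator Σ a_j(A,B)·n_k(A) over
individuals A and partners B, where n_k(A) is A's number of identified
associates in period k. Lags are measured between period midpoints in days.
Terms are pooled into non-overlapping moving-average windows accumulating a
target denominator (default 8,000 associations); accumulation runs over
distinct lags so windows are clean lag intervals, and a trailing partial
window is merged into the last full one. Each window is plotted at its
denominator-weighted mean lag. For permanent groups of constant size g with
full identification the rate is exactly 1/(g−1) at every lag (unit test).

Precision is estimated by a temporal jackknife omitting one sampling period at
a time, with replicate curves computed on the full curve's lag windows; the SE
is sqrt(((n−1)/n)·Σ(g'\_(i) − mean)²) over replicates in which the bin retains
a positive denominator (bins missing from any replicate are flagged). The
null rate permutes identities uniformly within each period — preserving group
sizes and identification counts — and recomputes the curve; in the
all-groups-of-two limit it approaches 1/(N−1) (tested).

Four social-dynamics models are fitted to the binned rates: a constant
("constant companions"), a single exponential decay ("casual acquaintances"),
constant plus decay, and a two-timescale double exponential (K = 1, 2, 3, 4
parameters). Per bin the numerator is modelled as
Binomial(denominator, model(τ̄)) — a quasi-likelihood, since the terms are not
independent — and parameters are estimated by bounded maximum likelihood
(L-BFGS-B, multiple starts; a, c ∈ [0,1], decay rates ≥ 0). Overdispersion
ĉ is the Pearson χ²/df of the most general (two-timescale) model, floored at
1 and shared across models; QAIC = −2 logL/ĉ + 2K and ΔQAIC ranks the
models. Whether the moving-average target counts numerator or denominator
terms, and which model anchors ĉ, are conventions of this package (the
denominator, and the most general model, respectively).

## Cluster delineation

Average-linkage agglomerative clustering runs on the dissimilarity 1 − index;
merge heights are reported on the index scale. The cophenetic correlation
coefficient (Pearson correlation between input and tree-implied indices)
guards against over-interpreting a dendrogram of a non-hierarchical society;
it is exactly 1 on ultrametric input and is verified against an independent
tree-traversal oracle.

Modularity of a division is the standard weighted Newman form

    Q = (1/2T) Σ_ij [a_ij − s_i s_j/(2T)] δ(c_i, c_j)

over ordered pairs including the i = j null term (two equal disconnected
cliques give exactly Q = 0.5; the implementation is cross-checked against
networkx and against exhaustive maximisation over all partitions for N ≤ 8).
Q > 0.3 is the conventional threshold for a meaningful division. The
gregariousness-corrected variant evaluates Q on the gregariousness-corrected
matrix, removing individual gregariousness from the null expectation; both
values are always reported and labelled.

Two delineation methods are provided: Newman's spectral method (recursive
bisection by the leading eigenvector of the generalised modularity matrix,
refined by greedy single-node moves, stopping when no split raises Q) and the
modularity-optimal dendrogram cut (candidate thresholds at midpoints between
consecutive merge heights; ties on Q go to fewer clusters; the full
threshold–Q curve is retained). Individuals left as singletons are reported
as their own cluster together with a nearest-cluster suggestion by mean index
— they are never silently reassigned, because folding an outlier into a
cluster is an analyst's judgement, not an algorithmic fact.

## Network metrics

Per individual: mean index, strength (row sum), eigenvector centrality
(unit-norm Perron vector, computed by power iteration and checked against a
dense eigendecomposition), reach (A·s), affinity (reach/strength), weighted
clustering coefficient Σ a_ij a_jk a_ki / (ceiling · Σ_{j≠k} a_ij a_ik) with
the ceiling set to the index's theoretical maximum of 1, and betweenness and
closeness on the graph with edge length 1/a_ij (unnormalised path counts;
closeness scaled as 100·(N−1)/Σ dist to land on a 0–100 range). The closeness
scaling and the clustering-coefficient ceiling are package conventions, chosen
so that association-index networks produce interpretable magnitudes; on a
disconnected graph closeness is computed within components and flagged.

## Social differentiation and index precision

Per-dyad joint counts are modelled as x ~ BetaBinomial(round(d), μ, θ) with d
the half-weight denominator rounded half-up (the denominators are half-integer
by construction; the rounding rule is a package convention).
Social differentiation S is the CV of the fitted Beta,
S = sqrt((1−μ)/(μ(1+θ))); S near 0 indicates a homogeneous society, near 1 a
well-differentiated one. The correlation between true and estimated indices
follows from the variance decomposition Var(x/d) = Var(p) + E[p(1−p)/d]:

    r = sqrt( Var(p) / (Var(p) + E[p(1−p)] · mean(1/d)) )

so r → 1 as sampling effort grows on any fixed society. Standard errors come
from a bootstrap over dyads (default 10,000 replicates; bootstrap refits are
warm-started from the point estimate). The likelihood is maximised by
Nelder-Mead on (logit μ, log θ) from six spread starts; at the degenerate
boundary (identical true probabilities) θ̂ → ∞ and Ŝ → 0, which the optimiser
reaches reliably (tested at 500 dyads, d = 50). Recovery: at true CV 1.0 and
mean denominator 30 the estimate lands within ±0.15 in well over 80% of
replicates, and is monotone across true CVs 0.2/0.6/1.0.

## Class comparisons, diel partitioning, fishery interactions

The Mantel class test correlates the dyadic index vector with a same-class
indicator and permutes individuals (simultaneous row/column relabelling);
t standardises the observed correlation against the permutation distribution,
and one-sided tails are reported alongside the two-sided p because "P"
conventions differ between packages. Classes with fewer than two members are
excluded with a warning.

Encounters are assigned to clusters by unique plurality of their retained
members' labels (an exact tie is "mixed-tie", no labelled member
"unassigned"). Diel bins use encounter start times only: morning
[07:00, 13:00], afternoon (13:00, 18:00], evening (18:00, 21:00]; times
outside the bins are excluded. Fisher's exact test (two-tailed, sum of tables
with point probability ≤ observed) contrasts morning vs evening counts for
the two largest clusters by default — the population's main social units.
scipy's implementation is used and cross-checked against exhaustive
hypergeometric enumeration in the tests.

Sex composition counts only groups with ≥ 2 known-sex members; a group is
mixed iff both sexes appear among them (unsexed members are ignored, so
"single-sex" is an underestimate by construction). Fishery summaries count an
encounter as an interaction when its trawler flag is not "none"; an encounter
flagged "both" counts once under each gear. Reported are per-individual
interaction counts and shares of all interactions, per-cluster mean ± SD and
range, and the per-gear breakdown.

## The synthetic society generator

The generator emulates the study system the pipeline targets: a small
resident coastal population in a few social clusters with strong
within-cluster and weak between-cluster association, cluster-specific diel
use of a core area, transient visitors, dependent calves, imperfect detection
and identification, and cluster-specific trawler-interaction propensities.
Per survey day and (time-bin, area) slot, each cluster holds a gathering with
its schedule's probability; members attend independently (default 0.75),
members of other clusters spill over rarely (default 0.01); attendees fuse
into one group (probability 0.35) or split uniformly into 2–4 subgroups; each
group is detected (0.9) and each member identified (0.9) independently.
Defaults are fixed at the regime the pipeline is designed for — clusters of
19/13/6 plus Poisson(2)/year transients, nine years of eight survey days,
yielding on the order of 110–140 restricted encounters and a mean of ~15
sightings per resident — and the diel schedule makes the largest cluster a
strict morning user of the core area and the second cluster evening-only
there.

Ground truth records the cluster labels and the true half-weight-scale
association probability per dyad: within-cluster w·i·(f + (1−f)·E[1/k])
(attendance × identification × same-subgroup probability; per-group detection
cancels from the index), exact when at most one gathering per cluster fires
per day; the between-cluster value is the first-order spill-over
approximation. The true differentiation S is the CV of that matrix.

What passing recovery tests shows — and does not. The generator produces
permanent cluster membership, independent attendance, and exchangeable
subgrouping. It does not produce temporally decaying associations (so model
selection on its output correctly favours the pure constant-companions
model), demographic turnover, spatially structured movement, or
identification errors that correlate with group size. Recovery results
(clustering ARI, permutation calibration, S recovery) therefore validate the
estimators' correctness under their stated assumptions, not their robustness
to every field complication.

## Problem sizes and numerical conventions

The library defaults mirror the full study conditions (20,000 permutations,
10,000 bootstrap replicates, 10,000 Mantel permutations, 8,000-association
windows). The test suite and the reproduction script use smaller replicate
counts chosen as desk-scale versions of the same designs: 2,000 permutations
and 300 bootstrap replicates in the script; 60 type-I-error replicates × 300
permutations, 30 clustering seeds, 30 S-recovery and 25 model-selection
replicates in the suite. Optimiser tolerances: Nelder-Mead xatol 1e-8 /
fatol 1e-10 (beta-binomial); L-BFGS-B with four spread starts and bounds
a, c ∈ [0, 1], b, d ∈ [0, 50] (SLAR models); probabilities clipped to
[1e-10, 1−1e-10] inside likelihoods. Ties on modularity go to fewer
clusters; the eigenvector sign convention assigns zero loadings to the
positive side. A single run seed is fanned out to per-stage child seeds via
`numpy.random.SeedSequence`, so each stage is independently reproducible.

## Known limitations

- The gregariousness-corrected modularity follows this package's definition
  (Q on the corrected matrix); other software may implement the correction
  differently, so corrected values are comparable within this package only.
- Betweenness/closeness conventions (edge length 1/a, ×100 closeness scaling,
  unnormalised betweenness) are stated conventions; absolute values are not
  comparable across packages, though rankings are.
- The beta-binomial S treats rounded half-weight denominators as binomial
  totals; for very sparse dyads the rounding bias is untested.
- The null association rate is defined by within-period identity permutation
  rather than an analytic formula; it converges to 1/(N−1) in the canonical
  limit but can differ from closed-form variants elsewhere.
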