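"""Population-level statistics: social differentiation and index precision,
Mantel class tests, encounter-to-cluster assignment, diel partitioning, sex
composition, and fishery-interaction summaries.

Social differentiation S is the coefficient of variation of the *true* dyadic
association probabilities; it is estimated by maximum likelihood under a
beta-binomial model of the per-dyad joint-sighting counts.  S near 0 means a
homogeneous society, near 1 a well-differentiated one.  The companion r
estimates the correlation between true and observed indices — how faithfully
the sampled matrix represents the real network.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .association import AssociationMatrix
from .records_io import EncounterTable

DIEL_BINS = {
    "morning": (dt.time(7, 0), dt.time(13, 0)),    # [07:00, 13:00]
    "afternoon": (dt.time(13, 1), dt.time(18, 0)),  # (13:00, 18:00]
    "evening": (dt.time(18, 1), dt.time(21, 0)),    # (18:00, 21:00]
}


class ConvergenceError(RuntimeError):
    """The beta-binomial likelihood optimiser failed to converge."""


@dataclass
class DifferentiationEstimate:
    """Maximum-likelihood social differentiation and sampling precision.

    ``s`` is the CV of the fitted Beta distribution of true association
    probabilities; ``r`` the model-implied correlation between true and
    estimated indices; standard errors come from a bootstrap over dyads.
    """

    s: float
    s_se: float
    r: float
    r_se: float
    mu: float
    theta: float
    n_dyads: int
    n_bootstrap: int
    log_likelihood: float

    def to_dict(self) -> dict:
        return {"S": self.s, "S_se": self.s_se, "r": self.r, "r_se": self.r_se,
                "mu": self.mu, "theta": self.theta, "n_dyads": self.n_dyads,
                "n_bootstrap": self.n_bootstrap,
                "log_likelihood": self.log_likelihood}


def _betabinom_nll(params: np.ndarray, x: np.ndarray, n: np.ndarray) -> float:
    logit_mu, log_theta = params
    mu = 1.0 / (1.0 + math.exp(-logit_mu))
    theta = math.exp(log_theta)
    ll = stats.betabinom.logpmf(x, n, mu * theta, (1.0 - mu) * theta)
    return -float(ll.sum())


def _fit_betabinom(x: np.ndarray, n: np.ndarray,
                   start: tuple[float, float] | None = None) -> tuple[float, float, float]:
    mu0 = float(np.clip(x.sum() / n.sum(), 1e-4, 1 - 1e-4))
    if start is not None:  # warm start (bootstrap replicates)
        starts = [[math.log(start[0] / (1 - start[0])),
                   math.log(max(start[1], 1e-6))]]
    else:
        starts = [[math.log(mu0 / (1 - mu0)), lt]
                  for lt in (-1.0, 0.5, 2.0, 4.0, 7.0, 10.0)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _betabinom_nll, x0, args=(x, n), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(f"beta-binomial fit failed: {best}")
    logit_mu, log_theta = best.x
    mu = 1.0 / (1.0 + math.exp(-logit_mu))
    theta = math.exp(min(log_theta, 25.0))
    return mu, theta, -best.fun


def _s_r_from_fit(mu: float, theta: float, n: np.ndarray) -> tuple[float, float]:
    var_p = mu * (1 - mu) / (1 + theta)
    s = math.sqrt(var_p) / mu
    e_pq = mu * (1 - mu) * theta / (1 + theta)
    noise = e_pq * float(np.mean(1.0 / n))
    r = math.sqrt(var_p / (var_p + noise)) if var_p + noise > 0 else 0.0
    return s, r


def social_differentiation(counts, n_bootstrap: int = 10_000,
                           seed: int | None = None,
                           min_dyads: int = 10) -> DifferentiationEstimate:
    """Estimate social differentiation S and index precision r.

    Per dyad, the joint-sighting count x is modelled as
    BetaBinomial(round(d), mu, theta) with d the half-weight denominator
    (rounded half-up to an integer).  S = CV of the fitted Beta; r follows from
    the variance decomposition Var(x/d) = Var(p) + E[p(1-p)/d], so
    r = sqrt(Var(p) / (Var(p) + E[p(1-p)] * mean(1/d))).  SEs are bootstrap
    standard deviations over dyad resamples.
    """
    d = counts.denominator
    iu = np.triu_indices(len(counts.ids), k=1)
    d_flat = d[iu]
    x_flat = counts.x[iu].astype(int)
    ok = d_flat > 0
    x = x_flat[ok]
    n = np.floor(d_flat[ok] + 0.5).astype(int)  # round half-up
    n = np.maximum(n, x)
    if len(x) < min_dyads:
        raise ValueError(f"need >= {min_dyads} dyads with positive denominator")

    mu, theta, ll = _fit_betabinom(x, n)
    s, r = _s_r_from_fit(mu, theta, n)

    rng = np.random.default_rng(seed)
    s_bs, r_bs = [], []
    for _ in range(n_bootstrap):
        pick = rng.integers(0, len(x), size=len(x))
        try:
            mu_b, theta_b, _ = _fit_betabinom(x[pick], n[pick], start=(mu, theta))
        except ConvergenceError:
            continue
        sb, rb = _s_r_from_fit(mu_b, theta_b, n[pick])
        s_bs.append(sb)
        r_bs.append(rb)
    s_se = float(np.std(s_bs, ddof=1)) if len(s_bs) > 1 else math.nan
    r_se = float(np.std(r_bs, ddof=1)) if len(r_bs) > 1 else math.nan
    return DifferentiationEstimate(s=s, s_se=s_se, r=r, r_se=r_se, mu=mu,
                                   theta=theta, n_dyads=len(x),
                                   n_bootstrap=n_bootstrap, log_likelihood=ll)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    """Matrix correlation between association and same-class structure."""

    r_observed: float
    t: float
    p_two_sided: float
    p_greater: float
    p_less: float
    n_permutations: int
    seed: int | None
    excluded_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"r_observed": self.r_observed, "t": self.t,
                "p_two_sided": self.p_two_sided, "p_greater": self.p_greater,
                "p_less": self.p_less, "n_permutations": self.n_permutations,
                "seed": self.seed, "excluded_classes": self.excluded_classes}


def mantel_class_test(m: AssociationMatrix, classes: dict[str, str],
                      n_perm: int = 10_000, seed: int | None = None) -> MantelResult:
    """Mantel test of within- vs between-class association.

    The statistic is the Pearson correlation between the dyadic index vector
    and the same-class indicator vector; the null permutes individuals
    (simultaneous row/column relabelling).  t standardises the observed
    correlation against the permutation distribution; both tails are reported
    because "P" conventions differ between packages.
    """
    counts: dict[str, int] = {}
    for i in m.ids:
        c = classes.get(i)
        if c is not None:
            counts[c] = counts.get(c, 0) + 1
    excluded = sorted([c for c, k in counts.items() if k < 2])
    keep = [i for i in m.ids if classes.get(i) in counts
            and counts[classes[i]] >= 2]
    if len(set(classes[i] for i in keep)) < 2:
        raise ValueError("need at least two classes with >= 2 members")
    if excluded:
        warnings.warn(f"classes with < 2 members excluded: {excluded}",
                      RuntimeWarning, stacklevel=2)
    idx = [m.ids.index(i) for i in keep]
    a = m.values[np.ix_(idx, idx)]
    lab = np.array([classes[i] for i in keep])
    iu = np.triu_indices(len(keep), k=1)
    va = a[iu]

    def corr(labels: np.ndarray) -> float:
        same = (labels[:, None] == labels[None, :])[iu].astype(float)
        sa, ss = va.std(), same.std()
        if sa == 0 or ss == 0:
            return 0.0
        return float(np.corrcoef(va, same)[0, 1])

    r_obs = corr(lab)
    rng = np.random.default_rng(seed)
    r_perm = np.array([corr(rng.permutation(lab)) for _ in range(n_perm)])
    sd = r_perm.std(ddof=1)
    t = (r_obs - r_perm.mean()) / sd if sd > 0 else math.inf
    return MantelResult(
        r_observed=r_obs, t=float(t),
        p_two_sided=float(np.mean(np.abs(r_perm) >= abs(r_obs))),
        p_greater=float(np.mean(r_perm >= r_obs)),
        p_less=float(np.mean(r_perm <= r_obs)),
        n_permutations=n_perm, seed=seed, excluded_classes=excluded)


# ---------------------------------------------------------------------------
# Encounter classification, diel partitioning
# ---------------------------------------------------------------------------

def classify_encounter_cluster(members, labels: dict[str, int]) -> int | str:
    """Assign a group to the cluster forming its unique plurality of members.

    Members without a label (unretained animals) are ignored.  An exact tie for
    the largest share returns ``"mixed-tie"``; a group with no labelled member
    returns ``"unassigned"``.
    """
    tally: dict[int, int] = {}
    for ind in members:
        c = labels.get(ind)
        if c is not None:
            tally[c] = tally.get(c, 0) + 1
    if not tally:
        return "unassigned"
    top = max(tally.values())
    winners = [c for c, k in tally.items() if k == top]
    return winners[0] if len(winners) == 1 else "mixed-tie"


def time_bin(t: dt.time) -> str | None:
    for name, (lo, hi) in DIEL_BINS.items():
        if lo <= t <= hi:
            return name
    return None


@dataclass
class DielTable:
    """Per-cluster encounter counts by time-of-day bin, with Fisher's test.

    ``fisher_p`` is the two-tailed Fisher exact p on the 2x2 morning-vs-evening
    table for ``tested_clusters``.
    """

    counts: pd.DataFrame
    scope: str
    tested_clusters: tuple
    fisher_table: list[list[int]]
    fisher_p: float


def diel_counts(table: EncounterTable, labels: dict[str, int],
                scope: str = "entire") -> pd.DataFrame:
    """Classified-encounter counts per cluster and diel bin."""
    if scope not in ("entire", "core"):
        raise ValueError("scope must be 'entire' or 'core'")
    enc = table.encounters
    if scope == "core":
        enc = enc[enc["area"] == "core"]
    members = table.memberships.groupby("encounter_id")["individual_id"].agg(list)
    rows = []
    for eid, t in zip(enc["encounter_id"], enc["time_start"]):
        cluster = classify_encounter_cluster(members.get(eid, []), labels)
        b = time_bin(t)
        if b is None or not isinstance(cluster, int):
            continue
        rows.append({"cluster": cluster, "bin": b})
    if not rows:
        return pd.DataFrame(0, index=pd.Index([], name="cluster"),
                            columns=list(DIEL_BINS))
    df = pd.DataFrame(rows)
    out = (df.groupby(["cluster", "bin"]).size().unstack(fill_value=0)
           .reindex(columns=list(DIEL_BINS), fill_value=0))
    out.index.name = "cluster"
    return out


def diel_partition_test(table: EncounterTable, labels: dict[str, int],
                        scope: str = "entire",
                        test_clusters: tuple | None = None) -> DielTable:
    """Fisher's exact test of diel partitioning between two clusters.

    Encounters are assigned to clusters by the plurality rule and bucketed by
    start time (morning [07:00, 13:00], afternoon (13:00, 18:00], evening
    (18:00, 21:00]).  The 2x2 test contrasts morning vs evening counts for the
    two clusters — by default the two with the most members (the population's
    main social units), provided both have classified encounters.
    """
    counts = diel_counts(table, labels, scope)
    if counts.empty:
        raise ValueError("no classifiable encounters within the diel bins")
    if test_clusters is None:
        sizes: dict[int, int] = {}
        for c in labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        present = [c for c in sorted(sizes, key=lambda c: (-sizes[c], c))
                   if c in counts.index and counts.loc[c].sum() > 0]
        if len(present) < 2:
            raise ValueError("need encounters from at least two clusters")
        test_clusters = tuple(sorted(present[:2]))
    a, b = test_clusters
    for c in (a, b):
        if c not in counts.index or counts.loc[c].sum() == 0:
            raise ValueError(f"cluster {c} has zero classifiable encounters")
    tab = [[int(counts.loc[a, "morning"]), int(counts.loc[a, "evening"])],
           [int(counts.loc[b, "morning"]), int(counts.loc[b, "evening"])]]
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return DielTable(counts=counts, scope=scope, tested_clusters=(a, b),
                     fisher_table=tab, fisher_p=float(p))


# ---------------------------------------------------------------------------
# Sex composition and fishery interactions
# ---------------------------------------------------------------------------

@dataclass
class SexComposition:
    """Group sex-class proportions among groups with >= 2 known-sex members."""

    n_groups: int
    n_male_only: int
    n_female_only: int
    n_mixed: int

    @property
    def pct_mixed(self) -> float:
        return 100.0 * self.n_mixed / self.n_groups if self.n_groups else math.nan

    def to_dict(self) -> dict:
        return {"n_groups": self.n_groups, "n_male_only": self.n_male_only,
                "n_female_only": self.n_female_only, "n_mixed": self.n_mixed,
                "pct_mixed": self.pct_mixed}


def sex_composition(table: EncounterTable, labels: dict[str, int] | None = None,
                    cluster: int | None = None) -> SexComposition:
    """Classify groups as male-only, female-only, or mixed.

    Only groups with at least two known-sex members count; unsexed members are
    ignored (a "single-sex" group with unsexed animals may of course be mixed).
    With ``cluster`` given, only groups composed solely of that cluster's
    labelled members are considered.
    """
    sex = dict(zip(table.registry["individual_id"], table.registry["sex"]))
    members = table.memberships.groupby("encounter_id")["individual_id"].agg(list)
    n_groups = n_m = n_f = n_mix = 0
    for eid in table.encounters["encounter_id"]:
        mem = members.get(eid, [])
        if cluster is not None:
            in_cluster = [labels.get(i) == cluster for i in mem if labels.get(i) is not None]
            if not in_cluster or not all(in_cluster):
                continue
        known = [sex.get(i, "U") for i in mem if sex.get(i, "U") in ("M", "F")]
        if len(known) < 2:
            continue
        n_groups += 1
        has_m, has_f = "M" in known, "F" in known
        if has_m and has_f:
            n_mix += 1
        elif has_m:
            n_m += 1
        else:
            n_f += 1
    return SexComposition(n_groups=n_groups, n_male_only=n_m,
                          n_female_only=n_f, n_mixed=n_mix)


@dataclass
class FisheryReport:
    """Trawler-interaction summary: per individual, per cluster, per gear."""

    n_interactions: int
    per_individual: pd.DataFrame
    per_cluster: pd.DataFrame
    gear_counts: dict[str, int]

    def gear_pct(self, gear: str) -> float:
        if self.n_interactions == 0:
            return math.nan
        return 100.0 * self.gear_counts[gear] / self.n_interactions


def fishery_interaction_summary(table: EncounterTable,
                                labels: dict[str, int]) -> FisheryReport:
    """Summarise dolphin-trawler interaction encounters.

    Interactions are encounters whose trawler flag is not "none".  Per
    individual: the number and share of all interaction encounters they were
    recorded in.  Per cluster: mean, SD and range of members' interaction
    counts.  Gear counts tally "both" once under each gear.
    """
    enc = table.encounters
    inter = enc[enc["trawler"] != "none"]
    n_total = len(inter)
    gear = {
        "pair": int(inter["trawler"].isin(["pair", "both"]).sum()),
        "bottom": int(inter["trawler"].isin(["bottom", "both"]).sum()),
    }
    members = table.memberships.groupby("encounter_id")["individual_id"].agg(list)
    counts = {i: 0 for i in labels}
    for eid in inter["encounter_id"]:
        for ind in members.get(eid, []):
            if ind in counts:
                counts[ind] += 1
    per_ind = pd.DataFrame({
        "individual_id": list(counts),
        "cluster": [labels[i] for i in counts],
        "n_interactions": [counts[i] for i in counts],
    })
    per_ind["proportion"] = (per_ind["n_interactions"] / n_total) if n_total else 0.0
    per_ind = per_ind.sort_values("individual_id").reset_index(drop=True)

    rows = []
    for c, sub in per_ind.groupby("cluster"):
        v = sub["n_interactions"].to_numpy(float)
        rows.append({"cluster": c, "n_individuals": len(v),
                     "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                     "min": int(v.min()), "max": int(v.max())})
    return FisheryReport(n_interactions=n_total, per_individual=per_ind,
                         per_cluster=pd.DataFrame(rows), gear_counts=gear)
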