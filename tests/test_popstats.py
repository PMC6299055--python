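"""Social differentiation, Mantel tests, diel partitioning, sex and fishery summaries."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from podnet import (AssociationMatrix, classify_encounter_cluster,
                    diel_partition_test, fishery_interaction_summary,
                    mantel_class_test, sex_composition, social_differentiation)
from podnet.popstats import (_betabinom_nll, _fit_betabinom, _s_r_from_fit,
                             diel_counts)

from conftest import build_table


# ---------------------------------------------------------------------------
# Social differentiation
# ---------------------------------------------------------------------------

class FakeCounts:
    """Minimal DyadCounts stand-in from explicit per-dyad (x, d) values.

    Pads to the next triangular size with zero-denominator dyads, which the
    estimator excludes.
    """

    def __init__(self, x, d):
        k = len(x)
        n = 2
        while n * (n - 1) // 2 < k:
            n += 1
        self.ids = [f"i{j}" for j in range(n)]
        self.x = np.zeros((n, n), dtype=int)
        dd = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        self.x[iu[0][:k], iu[1][:k]] = x
        self.x += self.x.T
        dd[iu[0][:k], iu[1][:k]] = d
        self.denominator = dd + dd.T


def test_homogeneous_society_gives_near_zero_s():
    rng = np.random.default_rng(0)
    n_dyads = 500
    d = np.full(n_dyads, 50)
    x = rng.binomial(50, 0.3, n_dyads)
    est = social_differentiation(FakeCounts(x, d), n_bootstrap=0, seed=1)
    assert est.s <= 0.05


def test_r_approaches_one_as_denominators_grow():
    mu, theta = 0.25, 3.0
    rs = [_s_r_from_fit(mu, theta, np.full(100, d))[1] for d in (5, 50, 5000)]
    assert rs[0] < rs[1] < rs[2]
    assert rs[2] > 0.99


def test_loglik_gradient_near_zero_at_optimum():
    rng = np.random.default_rng(5)
    p = rng.beta(2, 6, 300)
    d = np.full(300, 40)
    x = rng.binomial(40, p)
    mu, theta, _ = _fit_betabinom(x, d)
    opt = np.array([math.log(mu / (1 - mu)), math.log(theta)])
    eps = 1e-5
    for k in range(2):
        step = np.zeros(2)
        step[k] = eps
        grad = (_betabinom_nll(opt + step, x, d)
                - _betabinom_nll(opt - step, x, d)) / (2 * eps)
        assert abs(grad) < 0.5  # flat to numerical precision at this scale


def test_bootstrap_se_reported_and_seeded():
    rng = np.random.default_rng(2)
    p = rng.beta(1.5, 5, 200)
    d = rng.integers(20, 40, 200)
    x = rng.binomial(d, p)
    a = social_differentiation(FakeCounts(x, d), n_bootstrap=30, seed=9)
    b = social_differentiation(FakeCounts(x, d), n_bootstrap=30, seed=9)
    assert a.s_se == b.s_se and a.r_se == b.r_se
    assert a.s_se > 0 and 0 <= a.r <= 1


def test_too_few_dyads_rejected():
    with pytest.raises(ValueError, match="dyads"):
        social_differentiation(FakeCounts([1, 2, 1], [5, 5, 5]), n_bootstrap=0)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def block_matrix(n_each=5, within=0.6, between=0.05):
    n = 2 * n_each
    v = np.full((n, n), between)
    v[:n_each, :n_each] = within
    v[n_each:, n_each:] = within
    np.fill_diagonal(v, 0.0)
    return AssociationMatrix(ids=[f"i{k}" for k in range(n)], values=v)


def test_mantel_extreme_block_structure():
    # classes large enough that label permutations essentially never reproduce
    # the perfect block partition (2/C(16,8) chance per draw)
    m = block_matrix(n_each=8)
    classes = {f"i{k}": ("A" if k < 8 else "B") for k in range(16)}
    res = mantel_class_test(m, classes, n_perm=500, seed=0)
    assert res.t > 3
    assert res.p_greater <= 1 / 500 + 1e-12
    assert res.p_two_sided <= 1 / 500 + 1e-12


def test_mantel_seeded_reproducible_and_null_centred():
    rng = np.random.default_rng(8)
    v = rng.random((12, 12))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    m = AssociationMatrix(ids=[f"i{k}" for k in range(12)], values=v)
    classes = {f"i{k}": ("A" if k % 2 else "B") for k in range(12)}
    a = mantel_class_test(m, classes, n_perm=400, seed=3)
    b = mantel_class_test(m, classes, n_perm=400, seed=3)
    assert a.t == b.t and a.p_two_sided == b.p_two_sided
    # random labels on a random matrix: not significant
    assert a.p_two_sided > 0.01


def test_mantel_small_class_excluded():
    m = block_matrix()
    classes = {f"i{k}": ("A" if k < 5 else "B") for k in range(10)}
    classes["i9"] = "LONER"
    with pytest.warns(RuntimeWarning, match="LONER"):
        res = mantel_class_test(m, classes, n_perm=100, seed=0)
    assert res.excluded_classes == ["LONER"]


# ---------------------------------------------------------------------------
# Encounter classification and diel partitioning
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("members,expected", [
    (["a1", "a2", "a3", "a4", "a5"], 0),
    (["a1", "a2", "a3", "a4", "b1"], 0),     # majority rules
    (["a1", "a2", "b1", "b2"], "mixed-tie"),
    (["x", "y"], "unassigned"),
])
def test_classify_encounter_cluster(members, expected):
    labels = {f"a{k}": 0 for k in range(1, 6)} | {f"b{k}": 1 for k in range(1, 3)}
    assert classify_encounter_cluster(members, labels) == expected


def _diel_fixture(a_morning, a_evening, b_morning, b_evening):
    rows = []
    labels = {}
    for k in range(6):
        labels[f"A{k}"] = 0
        labels[f"B{k}"] = 1
    day = [0]

    def add(members, time):
        day[0] += 1
        rows.append({"date": f"2020-{(day[0] - 1) % 12 + 1:02d}-{(day[0] * 7) % 27 + 1:02d}",
                     "time": time, "members": members, "area": "core"})

    for _ in range(a_morning):
        add([f"A{k}" for k in range(4)], "09:00")
    for _ in range(a_evening):
        add([f"A{k}" for k in range(4)], "19:00")
    for _ in range(b_morning):
        add([f"B{k}" for k in range(4)], "10:00")
    for _ in range(b_evening):
        add([f"B{k}" for k in range(4)], "20:00")
    return build_table(rows), labels


def test_diel_partitioning_core_fixture_significant():
    table, labels = _diel_fixture(18, 0, 0, 8)
    res = diel_partition_test(table, labels, scope="core")
    assert res.fisher_table == [[18, 0], [0, 8]]
    assert res.fisher_p < 0.001


def test_diel_partitioning_entire_area_fixture_significant():
    table, labels = _diel_fixture(55, 4, 5, 10)
    res = diel_partition_test(table, labels, scope="entire")
    assert res.fisher_table == [[55, 4], [5, 10]]
    assert res.fisher_p < 0.001


def test_diel_uniform_times_not_significant():
    table, labels = _diel_fixture(10, 10, 10, 10)
    res = diel_partition_test(table, labels)
    assert res.fisher_p == pytest.approx(1.0)


def test_diel_counts_conserved():
    table, labels = _diel_fixture(7, 3, 2, 5)
    counts = diel_counts(table, labels, "core")
    assert counts.loc[0].sum() == 10
    assert counts.loc[1].sum() == 7
    assert counts.to_numpy().sum() == len(table.encounters)


def fisher_two_sided_enumeration(table):
    """Exhaustive hypergeometric two-tailed p: sum of all tables with point
    probability <= the observed one, at fixed margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def point(a_):
        return (comb(col1, a_, exact=True)
                * comb(n - col1, row1 - a_, exact=True)) / comb(n, row1, exact=True)

    p_obs = point(a)
    total = 0.0
    for a_ in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        p = point(a_)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


@pytest.mark.parametrize("table", [
    [[18, 0], [0, 8]],
    [[55, 4], [5, 10]],
    [[10, 10], [10, 10]],
    [[3, 17], [12, 5]],
    [[0, 9], [9, 0]],
    [[2, 1], [1, 2]],
])
def test_fisher_matches_exhaustive_enumeration(table):
    _, p_scipy = stats.fisher_exact(table, alternative="two-sided")
    assert p_scipy == pytest.approx(fisher_two_sided_enumeration(table), rel=1e-9)


# ---------------------------------------------------------------------------
# Sex composition and fishery interactions
# ---------------------------------------------------------------------------

def test_sex_composition_rules():
    reg = [{"individual_id": i, "sex": s, "is_calf": False}
           for i, s in [("m1", "M"), ("m2", "M"), ("f1", "F"), ("u1", "U")]]
    table = build_table([
        {"date": "2020-01-01", "members": ["m1", "m2", "u1"]},  # male-only
        {"date": "2020-01-02", "members": ["m1", "f1"]},        # mixed
        {"date": "2020-01-03", "members": ["m1", "u1"]},        # < 2 known-sex
    ], registry=reg)
    out = sex_composition(table)
    assert out.n_groups == 2
    assert out.n_male_only == 1
    assert out.n_mixed == 1


def test_sex_composition_proportion_fixture():
    # 60 qualifying groups of which 46 mixed -> 76.7%
    reg = [{"individual_id": i, "sex": s, "is_calf": False}
           for i, s in [("m1", "M"), ("m2", "M"), ("f1", "F"), ("f2", "F")]]
    rows = []
    for k in range(46):
        rows.append({"date": f"2020-{k % 12 + 1:02d}-{k % 27 + 1:02d}",
                     "time": f"{7 + k % 5}:00", "members": ["m1", "f1"]})
    for k in range(14):
        rows.append({"date": f"2021-{k % 12 + 1:02d}-{k % 27 + 1:02d}",
                     "time": f"{7 + k % 5}:30", "members": ["m1", "m2"]})
    out = sex_composition(build_table(rows, registry=reg))
    assert out.n_groups == 60
    assert out.n_mixed == 46
    assert out.pct_mixed == pytest.approx(76.7, abs=0.05)


def _fishery_fixture():
    labels = {"MOR": 0, "A2": 0, "B1": 1, "B2": 1}
    rows = []
    for k in range(22):  # pair-trawler interactions, MOR in 18 of all 35
        rows.append({"date": f"2020-{k % 12 + 1:02d}-{k % 27 + 1:02d}",
                     "trawler": "pair",
                     "members": ["MOR", "A2"] if k < 18 else ["A2"]})
    for k in range(13):  # bottom-trawler interactions
        rows.append({"date": f"2021-{k % 12 + 1:02d}-{k % 27 + 1:02d}",
                     "trawler": "bottom", "members": ["A2"]})
    rows.append({"date": "2021-12-20", "members": ["B1", "B2"]})  # no trawler
    return build_table(rows), labels


def test_fishery_gear_breakdown_and_individual_share():
    table, labels = _fishery_fixture()
    rep = fishery_interaction_summary(table, labels)
    assert rep.n_interactions == 35
    assert rep.gear_counts == {"pair": 22, "bottom": 13}
    assert rep.gear_pct("pair") == pytest.approx(62.9, abs=0.05)
    mor = rep.per_individual.set_index("individual_id").loc["MOR"]
    assert mor["proportion"] == pytest.approx(18 / 35)
    assert mor["proportion"] > 0.5


def test_fishery_cluster_without_interactions():
    table, labels = _fishery_fixture()
    rep = fishery_interaction_summary(table, labels)
    row = rep.per_cluster.set_index("cluster").loc[1]
    assert row["mean"] == 0.0
    assert row["min"] == 0 and row["max"] == 0


def test_fishery_both_gear_counted_once_per_gear():
    labels = {"X": 0}
    table = build_table([
        {"date": "2020-01-01", "trawler": "both", "members": ["X"]},
        {"date": "2020-01-02", "trawler": "pair", "members": ["X"]},
    ])
    rep = fishery_interaction_summary(table, labels)
    assert rep.n_interactions == 2
    assert rep.gear_counts == {"pair": 2, "bottom": 1}
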