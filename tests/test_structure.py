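"""Dendrograms with cophenetic validation, modularity, and community detection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from podnet import (AssociationMatrix, average_linkage, best_dendrogram_cut,
                    best_partition_exhaustive, eigenvector_communities,
                    modularity)
from podnet.structure import cophenetic_index_matrix


def mat(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"i{k}" for k in range(len(values))]
    return AssociationMatrix(ids=list(ids), values=values)


def random_sym(rng, n, scale=0.5):
    v = rng.random((n, n)) * scale
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v


def two_cliques(n_each=4, w=1.0):
    n = 2 * n_each
    v = np.zeros((n, n))
    for block in (range(n_each), range(n_each, n)):
        for i, j in itertools.combinations(block, 2):
            v[i, j] = v[j, i] = w
    return mat(v)


def test_hand_agglomeration_order():
    m = mat([[0, 0.9, 0.1], [0.9, 0, 0.1], [0.1, 0.1, 0]], ids=list("ABC"))
    d = average_linkage(m)
    heights = sorted(d.merge_heights, reverse=True)
    assert heights[0] == pytest.approx(0.9)   # A and B merge first
    assert heights[1] == pytest.approx(0.1)   # C joins at the A/B-to-C mean
    labels = d.cut(0.5)
    assert labels["A"] == labels["B"] != labels["C"]


def test_ccc_is_one_for_ultrametric_input():
    # a perfectly hierarchical (ultrametric) similarity structure
    v = np.array([
        [0.0, 0.8, 0.3, 0.3],
        [0.8, 0.0, 0.3, 0.3],
        [0.3, 0.3, 0.0, 0.6],
        [0.3, 0.3, 0.6, 0.0],
    ])
    d = average_linkage(mat(v))
    assert d.ccc == pytest.approx(1.0, abs=1e-12)


def test_ccc_against_independent_tree_oracle():
    rng = np.random.default_rng(17)
    m = mat(random_sym(rng, 9))
    d = average_linkage(m)

    # oracle: walk the merge tree; a pair's cophenetic index is the height of
    # the merge that first unites them
    n = m.n
    clusters = {k: {k} for k in range(n)}
    coph = np.zeros((n, n))
    for step, (a, b, dist, _) in enumerate(d.linkage):
        ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
        for i in ca:
            for j in cb:
                coph[i, j] = coph[j, i] = 1.0 - dist
        clusters[n + step] = ca | cb

    assert np.allclose(cophenetic_index_matrix(d), coph, atol=1e-12)
    iu = np.triu_indices(n, k=1)
    expect = np.corrcoef(m.values[iu], coph[iu])[0, 1]
    assert d.ccc == pytest.approx(expect, abs=1e-12)


def test_leaf_permutation_gives_same_tree():
    rng = np.random.default_rng(3)
    v = random_sym(rng, 7)
    m = mat(v)
    d = average_linkage(m)
    order = rng.permutation(7)
    m2 = AssociationMatrix(ids=[m.ids[i] for i in order],
                           values=v[np.ix_(order, order)])
    d2 = average_linkage(m2)
    assert np.allclose(np.sort(d.merge_heights), np.sort(d2.merge_heights))
    c1 = cophenetic_index_matrix(d)
    c2 = cophenetic_index_matrix(d2)
    back = {i: k for k, i in enumerate(m2.ids)}
    remap = [back[i] for i in m.ids]
    assert np.allclose(c1, c2[np.ix_(remap, remap)], atol=1e-12)


def test_modularity_single_cluster_is_zero():
    rng = np.random.default_rng(1)
    m = mat(random_sym(rng, 6))
    assert modularity(m, {i: 0 for i in m.ids}) == pytest.approx(0.0, abs=1e-12)


def test_modularity_two_equal_cliques_is_half():
    m = two_cliques(4, 1.0)
    labels = {i: (0 if k < 4 else 1) for k, i in enumerate(m.ids)}
    assert modularity(m, labels) == pytest.approx(0.5, abs=1e-12)


def test_modularity_matches_networkx():
    rng = np.random.default_rng(9)
    v = random_sym(rng, 8)
    m = mat(v)
    labels = {i: int(k % 3) for k, i in enumerate(m.ids)}
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    for a, b in itertools.combinations(range(8), 2):
        if v[a, b] > 0:
            g.add_edge(m.ids[a], m.ids[b], weight=v[a, b])
    communities = [{i for i in m.ids if labels[i] == c} for c in range(3)]
    expect = nx.community.modularity(g, communities, weight="weight")
    assert modularity(m, labels) == pytest.approx(expect, abs=1e-12)


def test_modularity_invariant_to_uniform_scaling():
    rng = np.random.default_rng(12)
    v = random_sym(rng, 7)
    labels = {f"i{k}": k % 2 for k in range(7)}
    q1 = modularity(mat(v), labels)
    q2 = modularity(mat(v * 7.3), labels)
    assert q1 == pytest.approx(q2, abs=1e-12)


def test_eigenvector_uniform_matrix_single_cluster():
    v = np.full((6, 6), 0.4)
    np.fill_diagonal(v, 0.0)
    out = eigenvector_communities(mat(v))
    assert out.n_clusters == 1


def test_eigenvector_recovers_two_cliques():
    m = two_cliques(4, 1.0)
    out = eigenvector_communities(m)
    assert out.n_clusters == 2
    assert out.modularity_q == pytest.approx(0.5, abs=1e-12)
    left = {out.labels[i] for i in m.ids[:4]}
    right = {out.labels[i] for i in m.ids[4:]}
    assert len(left) == len(right) == 1 and left != right


@pytest.mark.parametrize("seed", range(6))
def test_eigenvector_matches_exhaustive_optimum(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(5, 8))
    # planted two-block structure plus noise keeps the optimum well-defined
    v = random_sym(rng, n, scale=0.1)
    half = n // 2
    for i, j in itertools.combinations(range(half), 2):
        v[i, j] = v[j, i] = 0.6 + 0.2 * rng.random()
    for i, j in itertools.combinations(range(half, n), 2):
        v[i, j] = v[j, i] = 0.6 + 0.2 * rng.random()
    m = mat(v)
    spectral = eigenvector_communities(m)
    exact = best_partition_exhaustive(m)
    assert spectral.modularity_q == pytest.approx(exact.modularity_q, abs=1e-9)


def test_best_cut_two_cliques_threshold_between_levels():
    # within-clique index 0.8, between 0.05
    v = np.full((8, 8), 0.05)
    for block in (range(4), range(4, 8)):
        for i, j in itertools.combinations(block, 2):
            v[i, j] = v[j, i] = 0.8
    np.fill_diagonal(v, 0.0)
    m = mat(v)
    cut = best_dendrogram_cut(average_linkage(m), m)
    assert cut.n_clusters == 2
    assert 0.05 < cut.cut_index < 0.8
    assert cut.modularity_q == pytest.approx(
        max(q for _, q in cut.modularity_curve))


def test_best_cut_is_argmax_of_curve(paper_society):
    m = paper_society["hwi"]
    cut = best_dendrogram_cut(average_linkage(m), m)
    qs = [q for _, q in cut.modularity_curve]
    assert cut.modularity_q >= max(qs) - 1e-12


def test_eigenvector_q_not_below_best_cut(paper_society):
    m = paper_society["hwi"]
    ev = eigenvector_communities(m)
    cut = best_dendrogram_cut(average_linkage(m), m)
    assert ev.modularity_q >= cut.modularity_q - 1e-9


def test_singleton_gets_nearest_cluster_suggestion():
    # an outlier left as its own cluster is reported with the cluster it is
    # closest to by mean index, never silently reassigned
    from podnet.structure import ClusterAssignment, _suggest_singletons

    v = np.zeros((9, 9))
    for block in (range(4), range(4, 8)):
        for i, j in itertools.combinations(block, 2):
            v[i, j] = v[j, i] = 0.8
    v[8, 0] = v[0, 8] = 0.03          # weak tie to the first clique only
    m = mat(v)
    labels = {m.ids[k]: (0 if k < 4 else 1 if k < 8 else 2) for k in range(9)}
    assign = ClusterAssignment(labels=labels, modularity_q=0.0, method="manual")
    _suggest_singletons(assign, m)
    assert assign.labels["i8"] == 2            # label untouched
    assert assign.singleton_suggestions == {"i8": 0}


def test_newick_export_round_trips_leaves():
    import dendropy

    rng = np.random.default_rng(2)
    m = mat(random_sym(rng, 6))
    d = average_linkage(m)
    tree = dendropy.Tree.get(data=d.to_newick(), schema="newick")
    leaves = sorted(t.taxon.label for t in tree.leaf_node_iter())
    assert leaves == sorted(m.ids)
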