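"""Social-cluster delineation: average-linkage dendrograms with cophenetic
validation, weighted Newman modularity (plain and gregariousness-corrected),
eigenvector community detection, and modularity-optimal dendrogram cuts.

Association matrices are similarities in [0, 1]; hierarchical clustering runs
on the dissimilarity 1 - index, with all reported merge heights mapped back to
the association-index scale.  Modularity Q compares within-cluster association
to the strength-based random expectation; values above ~0.3 conventionally
indicate a meaningful division.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .association import AssociationMatrix, hwig


@dataclass
class Dendrogram:
    """Average-linkage merge tree on the association-index scale.

    ``linkage`` is a scipy linkage matrix on the 1 - index distance scale;
    ``merge_heights`` are the same merges expressed as association indices
    (non-increasing along successive merges).  ``ccc`` is the cophenetic
    correlation coefficient between input and tree-implied indices.
    """

    ids: list[str]
    linkage: np.ndarray
    ccc: float

    @property
    def merge_heights(self) -> np.ndarray:
        return 1.0 - self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, index_threshold: float) -> dict[str, int]:
        """Cluster labels from cutting at an association-index threshold.

        Pairs merging at index >= threshold stay together.
        """
        flat = hierarchy.fcluster(self.linkage, t=1.0 - index_threshold,
                                  criterion="distance")
        return {i: int(c) for i, c in zip(self.ids, flat)}

    def to_newick(self) -> str:
        """Newick string with branch lengths on the 1 - index (distance) scale."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6f}"
            l = rec(node.left, node.dist)
            r = rec(node.right, node.dist)
            return f"({l},{r}):{length:.6f}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


@dataclass
class ClusterAssignment:
    """Per-individual cluster labels with the modularity of the division."""

    labels: dict[str, int]
    modularity_q: float
    method: str
    gregariousness_corrected: bool = False
    cut_index: float | None = None
    modularity_curve: list[tuple[float, float]] | None = None
    singleton_suggestions: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def label_vector(self, ids: list[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])


# ---------------------------------------------------------------------------
# Dendrogram + CCC
# ---------------------------------------------------------------------------

def cophenetic_index_matrix(d: Dendrogram) -> np.ndarray:
    """Tree-implied pairwise association indices (1 - cophenetic distance)."""
    coph = hierarchy.cophenet(d.linkage)
    out = 1.0 - squareform(coph)
    np.fill_diagonal(out, 0.0)
    return out


def average_linkage(m: AssociationMatrix) -> Dendrogram:
    """Agglomerative average-linkage clustering of the association matrix.

    Merging happens on dissimilarity 1 - index; average linkage equals the mean
    pairwise index between the merged sets.  The cophenetic correlation
    coefficient (CCC) is the Pearson correlation between the input indices and
    the tree-implied (cophenetic) indices — values near 1 certify that the
    dendrogram faithfully represents the matrix.
    """
    if m.n < 2:
        raise ValueError("need at least two individuals")
    dist = squareform(np.clip(1.0 - m.values, 0.0, None), checks=False)
    Z = hierarchy.linkage(dist, method="average")
    coph = hierarchy.cophenet(Z)
    if np.ptp(coph) == 0 or np.ptp(dist) == 0:
        ccc = 1.0 if np.allclose(coph, dist) else 0.0
    else:
        ccc = float(pearsonr(dist, coph)[0])
    return Dendrogram(ids=list(m.ids), linkage=Z, ccc=ccc)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def _matrix_for(m: AssociationMatrix, gregariousness_corrected: bool) -> np.ndarray:
    if gregariousness_corrected:
        return m.values if m.flavor == "HWIG" else hwig(m).values
    return m.values


def modularity(m: AssociationMatrix, labels: dict[str, int],
               gregariousness_corrected: bool = False) -> float:
    """Weighted Newman modularity of a division.

    Q = (1/2T) * sum_ij [a_ij - s_i s_j / (2T)] delta(c_i, c_j) over ordered
    pairs, with s the row strengths and 2T the total (ordered) weight.  The
    gregariousness-corrected variant evaluates Q on the HWIG-rescaled matrix,
    removing the contribution of individual gregariousness to the expectation.
    """
    a = _matrix_for(m, gregariousness_corrected)
    missing = [i for i in m.ids if i not in labels]
    if missing:
        raise KeyError(f"labels missing for: {missing}")
    two_t = a.sum()
    if two_t == 0:
        raise ValueError("total association weight is zero")
    s = a.sum(axis=1)
    lab = np.array([labels[i] for i in m.ids])
    q = 0.0
    for c in np.unique(lab):
        sel = lab == c
        q += a[np.ix_(sel, sel)].sum() - s[sel].sum() ** 2 / two_t
    return float(q / two_t)


def _leading_eigenvector(b: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(b)
    return vecs[:, -1]


def _fine_tune(s: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Greedy single-node sign flips increasing s^T B s."""
    s = s.copy()
    for _ in range(len(s) ** 2):
        bs = b @ s
        gains = -4.0 * s * bs + 4.0 * np.diag(b)
        i = int(np.argmax(gains))
        if gains[i] <= 1e-12:
            break
        s[i] = -s[i]
    return s


def eigenvector_communities(m: AssociationMatrix,
                            gregariousness_corrected: bool = False) -> ClusterAssignment:
    """Newman's spectral community detection on the weighted modularity matrix.

    Recursive bisection by the sign of the leading eigenvector of the
    (generalised) modularity matrix, refined by greedy single-node moves;
    splitting stops when no division increases Q.  A uniform matrix yields a
    single cluster.
    """
    a = _matrix_for(m, gregariousness_corrected)
    n = m.n
    if n < 2:
        raise ValueError("need at least two individuals")
    s_str = a.sum(axis=1)
    two_t = a.sum()
    if two_t == 0:
        raise ValueError("total association weight is zero")
    b_full = a - np.outer(s_str, s_str) / two_t

    labels = np.zeros(n, dtype=int)
    next_label = [1]

    def split(indices: np.ndarray) -> None:
        if len(indices) < 2:
            return
        bg = b_full[np.ix_(indices, indices)].copy()
        bg -= np.diag(bg.sum(axis=1))
        v = _leading_eigenvector(bg)
        s = np.where(v >= 0, 1.0, -1.0)
        s = _fine_tune(s, bg)
        if np.all(s == s[0]):
            return
        dq = float(s @ bg @ s) / (2.0 * two_t)
        if dq <= 1e-12:
            return
        grp_a = indices[s > 0]
        grp_b = indices[s < 0]
        labels[grp_b] = next_label[0]
        next_label[0] += 1
        split(grp_a)
        split(grp_b)

    split(np.arange(n))
    lab = {i: int(l) for i, l in zip(m.ids, labels)}
    q = modularity(m, lab, gregariousness_corrected)
    out = ClusterAssignment(labels=lab, modularity_q=q, method="eigenvector",
                            gregariousness_corrected=gregariousness_corrected)
    _suggest_singletons(out, m)
    return out


def best_partition_exhaustive(m: AssociationMatrix,
                              gregariousness_corrected: bool = False) -> ClusterAssignment:
    """Exhaustive modularity maximisation over all set partitions (N <= 10).

    Brute-force oracle for validating the spectral method on small instances.
    """
    n = m.n
    if n > 10:
        raise ValueError("exhaustive search limited to N <= 10")

    def partitions(ids):
        if not ids:
            yield []
            return
        first, rest = ids[0], ids[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best_q, best_labels = -np.inf, None
    for part in partitions(list(m.ids)):
        lab = {i: c for c, block in enumerate(part) for i in block}
        q = modularity(m, lab, gregariousness_corrected)
        if q > best_q + 1e-15:
            best_q, best_labels = q, lab
    return ClusterAssignment(labels=best_labels, modularity_q=best_q,
                             method="exhaustive",
                             gregariousness_corrected=gregariousness_corrected)


def _suggest_singletons(assign: ClusterAssignment, m: AssociationMatrix) -> None:
    """For singleton clusters, record the nearest cluster by mean index.

    Outliers that no cluster claims (an individual merging only at a very low
    index) are kept as their own cluster, never silently reassigned; the
    suggestion documents where they would fold if forced.
    """
    sizes = assign.cluster_sizes()
    singles = [i for i, c in assign.labels.items() if sizes[c] == 1]
    idx = {i: k for k, i in enumerate(m.ids)}
    for s in singles:
        means = {}
        for c in sizes:
            if c == assign.labels[s] or sizes[c] == 1:
                continue
            members = [idx[i] for i, l in assign.labels.items() if l == c]
            means[c] = float(np.mean(m.values[idx[s], members]))
        if means:
            assign.singleton_suggestions[s] = max(means, key=means.get)


def best_dendrogram_cut(d: Dendrogram, m: AssociationMatrix,
                        gregariousness_corrected: bool = False) -> ClusterAssignment:
    """Pick the dendrogram cut maximising modularity.

    Candidate thresholds are midpoints between consecutive distinct merge
    heights (plus one below the lowest merge, yielding the single-cluster
    division).  Ties on Q go to the division with fewer clusters.  The full
    (threshold, Q) curve is retained for reporting.
    """
    heights = np.unique(d.merge_heights)
    candidates = [float(heights[0]) - 0.5 * max(float(heights[0]), 1e-6)]
    candidates += [float((a + b) / 2) for a, b in zip(heights[:-1], heights[1:])]
    candidates.append(float(heights[-1]) + (1.0 - float(heights[-1])) / 2 + 1e-9)

    curve = []
    best = None
    for t in candidates:
        lab = d.cut(t)
        q = modularity(m, lab, gregariousness_corrected)
        k = len(set(lab.values()))
        curve.append((t, q))
        if best is None or q > best[0] + 1e-12 or (abs(q - best[0]) <= 1e-12 and k < best[1]):
            best = (q, k, t, lab)
    q, _, t, lab = best
    out = ClusterAssignment(labels=lab, modularity_q=q, method="dendrogram_cut",
                            gregariousness_corrected=gregariousness_corrected,
                            cut_index=t, modularity_curve=curve)
    _suggest_singletons(out, m)
    return out
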