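"""Node- and cluster-level weighted network metrics.

Strength, reach, affinity, eigenvector centrality and the weighted clustering
coefficient are computed directly from the association matrix; betweenness and
closeness treat 1/index as an edge length, so strongly associated dyads are
"close".  Closeness is scaled by 100 to land on an interpretable 0-100 range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix

METRIC_COLUMNS = ["mean_index", "strength", "eigenvector_centrality", "reach",
                  "affinity", "clustering_coefficient", "betweenness", "closeness"]


def power_iteration_centrality(a: np.ndarray, tol: float = 1e-12,
                               max_iter: int = 10_000) -> np.ndarray:
    """Leading-eigenvector centrality of a symmetric non-negative matrix.

    Unit-norm, non-negative (Perron) vector by power iteration with a small
    uniform regulariser for reducible matrices.
    """
    n = a.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    shift = a + np.eye(n) * (a.max() * 1e-9 + 1e-15)
    for _ in range(max_iter):
        w = shift @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return v
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    return np.abs(v)


def _graph(m: AssociationMatrix) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    n = m.n
    for i in range(n):
        for j in range(i + 1, n):
            w = m.values[i, j]
            if w > 0:
                g.add_edge(m.ids[i], m.ids[j], weight=float(w), length=1.0 / float(w))
    return g


def node_metrics(m: AssociationMatrix, weight_ceiling: float = 1.0) -> pd.DataFrame:
    """Per-individual metrics table (one row per individual).

    strength s_i = sum_j a_ij; reach_i = sum_j a_ij s_j (= (A s)_i); affinity =
    reach/strength; weighted clustering coefficient
    C_i = sum_{j!=k} a_ij a_jk a_ki / (ceiling * sum_{j!=k} a_ij a_ik) with the
    ceiling the index's theoretical maximum (1 for association indices);
    betweenness uses unnormalised shortest-path counts on edge length 1/a;
    closeness_i = 100 (N-1) / sum_j dist(i, j) over reachable j.  On a
    disconnected graph closeness is computed within components and a warning is
    raised.
    """
    if m.n < 2:
        raise ValueError("need at least two individuals")
    a = m.values.astype(float)
    n = m.n
    s = a.sum(axis=1)
    reach = a @ s
    affinity = np.divide(reach, s, out=np.zeros_like(reach), where=s > 0)
    mean_index = s / (n - 1)

    evc = power_iteration_centrality(a)

    a3 = np.linalg.matrix_power(a, 3)
    tri = np.diag(a3)
    open_paths = s ** 2 - (a ** 2).sum(axis=1)
    cc = np.divide(tri, weight_ceiling * open_paths,
                   out=np.zeros_like(tri), where=open_paths > 0)

    g = _graph(m)
    betweenness = nx.betweenness_centrality(g, weight="length", normalized=False)
    closeness = {}
    disconnected = False
    for node in g.nodes:
        dists = nx.single_source_dijkstra_path_length(g, node, weight="length")
        total = sum(v for k, v in dists.items() if k != node)
        reachable = len(dists) - 1
        if reachable < n - 1:
            disconnected = True
        closeness[node] = 100.0 * (n - 1) / total if total > 0 else 0.0
    if disconnected:
        warnings.warn("association graph is disconnected; closeness computed "
                      "within components", RuntimeWarning, stacklevel=2)

    return pd.DataFrame({
        "individual_id": m.ids,
        "mean_index": mean_index,
        "strength": s,
        "eigenvector_centrality": evc,
        "reach": reach,
        "affinity": affinity,
        "clustering_coefficient": cc,
        "betweenness": [betweenness[i] for i in m.ids],
        "closeness": [closeness[i] for i in m.ids],
    }).set_index("individual_id")


def cluster_summary(table: pd.DataFrame, labels: dict[str, int]) -> pd.DataFrame:
    """Mean +/- SD of each metric per cluster, plus an overall column.

    Long-form output: one row per (cluster, metric) with mean, sd, n.
    """
    lab = pd.Series({i: labels[i] for i in table.index}, name="cluster")
    if lab.isna().any():
        raise KeyError("labels missing for some individuals")
    rows = []
    groups = list(table.groupby(lab)) + [("overall", table)]
    for name, sub in groups:
        if len(sub) == 0:
            raise ValueError(f"cluster {name} is empty")
        for metric in METRIC_COLUMNS:
            if metric not in table.columns:
                continue
            v = sub[metric].to_numpy(float)
            rows.append({"cluster": name, "metric": metric, "n": len(v),
                         "mean": float(v.mean()),
                         "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan})
    return pd.DataFrame(rows)


def export_graphml(m: AssociationMatrix, path, labels: dict[str, int] | None = None,
                   metrics: pd.DataFrame | None = None,
                   min_index: float | None = None) -> None:
    """Write the association network as GraphML with optional node attributes.

    ``min_index`` keeps only edges strictly above the threshold — pass
    ``2 * mean index`` to export only "meaningful" associations.
    """
    g = _graph(m)
    if min_index is not None:
        drop = [(u, v) for u, v, d in g.edges(data=True) if d["weight"] <= min_index]
        g.remove_edges_from(drop)
    if labels:
        nx.set_node_attributes(g, {i: int(c) for i, c in labels.items()}, "cluster")
    if metrics is not None:
        for col in metrics.columns:
            nx.set_node_attributes(g, {i: float(v) for i, v in metrics[col].items()}, col)
    nx.write_graphml(g, path)


def twice_mean_threshold(m: AssociationMatrix) -> float:
    """Twice the overall mean index — the conventional 'meaningful edge' filter."""
    return 2.0 * float(m.triu_values().mean())
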