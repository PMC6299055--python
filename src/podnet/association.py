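"""Dyadic association indices: half-weight (HWI) and its gregariousness
correction (HWIG).

The half-weight index estimates the probability that two individuals are
associated in a sampling period, down-weighting periods in which only one of
the two was identified — the least biased choice when not every group member
can be photographed.  HWIG rescales HWI by the dyad's joint gregariousness so
that individuals who simply associate with everyone do not dominate structure
analyses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records_io import PeriodMatrices


@dataclass
class DyadCounts:
    """Per-dyad tallies over sampling periods.

    For an unordered dyad (a, b): ``x`` counts periods in which both were
    identified and associated, ``both_seen`` periods in which both were
    identified (associated or not), and ``n_seen[i]`` the periods individual
    *i* was identified at all.  From these, y_ab = both_seen - x,
    y_a = n_seen[a] - both_seen, and the half-weight denominator
    d = x + y_ab + (y_a + y_b)/2.
    """

    ids: list[str]
    x: np.ndarray
    both_seen: np.ndarray
    n_seen: np.ndarray

    @property
    def y_ab(self) -> np.ndarray:
        return self.both_seen - self.x

    @property
    def denominator(self) -> np.ndarray:
        n = self.n_seen
        y_a = n[:, None] - self.both_seen
        y_b = n[None, :] - self.both_seen
        d = self.x + self.y_ab + 0.5 * (y_a + y_b)
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class AssociationMatrix:
    """Symmetric dyadic index matrix; diagonal stored as 0.

    ``flavor`` is "HWI" (entries in [0, 1]) or "HWIG" (may exceed 1).
    """

    ids: list[str]
    values: np.ndarray
    flavor: str = "HWI"

    @property
    def n(self) -> int:
        return len(self.ids)

    def triu_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries as a flat vector (i < j order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_edgelist(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n, k=1)
        return pd.DataFrame({
            "id_a": [self.ids[a] for a in i],
            "id_b": [self.ids[b] for b in j],
            "index": self.values[i, j],
        })


def dyad_counts(pm: PeriodMatrices) -> DyadCounts:
    """Tally joint and separate identifications for every dyad."""
    n = pm.n_individuals
    if n < 2:
        raise ValueError("need at least two individuals")
    x = np.zeros((n, n), dtype=np.int64)
    both = np.zeros((n, n), dtype=np.int64)
    seen_total = np.zeros(n, dtype=np.int64)
    for m, a in zip(pm.matrices, pm.association_matrices()):
        seen = m.any(axis=0)
        x += a
        both += np.outer(seen, seen)
        seen_total += seen
    np.fill_diagonal(x, 0)
    np.fill_diagonal(both, 0)
    return DyadCounts(ids=list(pm.ids), x=x, both_seen=both, n_seen=seen_total)


def hwi(counts: DyadCounts) -> AssociationMatrix:
    """Half-weight index HWI_ab = x / (x + y_ab + (y_a + y_b)/2).

    Dyads with a zero denominator (neither individual ever identified) are set
    to 0 with a warning.
    """
    d = counts.denominator
    zero = (d == 0)
    np.fill_diagonal(zero, False)
    if zero.any():
        warnings.warn(f"{int(zero.sum() // 2)} dyad(s) with zero denominator set to 0",
                      RuntimeWarning, stacklevel=2)
    values = np.divide(counts.x, d, out=np.zeros_like(d, dtype=float), where=d > 0)
    np.fill_diagonal(values, 0.0)
    return AssociationMatrix(ids=list(counts.ids), values=values, flavor="HWI")


def hwig(m: AssociationMatrix, scale: str = "index") -> AssociationMatrix:
    """Gregariousness-corrected index.

    The correction divides each dyad's HWI by its gregariousness-based
    expectation r_a * r_b / T (row sums over total ordered association),
    yielding the observed/expected ratio HWI_ab * T / (r_a * r_b)
    (``scale="ratio"``; values straddle 1 and may exceed it).  The default
    ``scale="index"`` multiplies that ratio by the mean index so the result
    stays on the association-index scale: for a matrix with all pairwise
    indices equal to h every corrected value is h * N/(N-1).  Dyads in a row
    with zero total association stay 0.
    """
    if m.flavor != "HWI":
        raise ValueError("hwig expects an HWI matrix")
    if scale not in ("index", "ratio"):
        raise ValueError("scale must be 'index' or 'ratio'")
    a = m.values
    n = m.n
    rows = a.sum(axis=1)
    total = a.sum()
    denom = np.outer(rows, rows)
    values = np.divide(a * total, denom, out=np.zeros_like(a), where=denom > 0)
    if scale == "index":
        values *= total / (n * (n - 1))
    np.fill_diagonal(values, 0.0)
    return AssociationMatrix(ids=list(m.ids), values=values, flavor="HWIG")


def class_mean_index(m: AssociationMatrix, classes: dict[str, str]) -> pd.DataFrame:
    """Mean +/- SD of the index within and between classes of individuals.

    One row per unordered class pair (within-class rows have class_a == class_b).
    A class with fewer than two members has no within-class dyads; its
    within-class mean is reported as missing.
    """
    labels = [classes.get(i) for i in m.ids]
    if any(l is None for l in labels):
        missing = [i for i, l in zip(m.ids, labels) if l is None]
        raise KeyError(f"no class label for individual(s): {missing}")
    uniq = sorted(set(labels))
    idx = {c: [k for k, l in enumerate(labels) if l == c] for c in uniq}
    rows = []
    for a, b in itertools.combinations_with_replacement(uniq, 2):
        if a == b:
            members = idx[a]
            vals = [m.values[i, j] for i, j in itertools.combinations(members, 2)]
        else:
            vals = [m.values[i, j] for i in idx[a] for j in idx[b]]
        vals = np.asarray(vals, dtype=float)
        rows.append({
            "class_a": a, "class_b": b, "n_dyads": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def write_matrix_csv(m: AssociationMatrix, path) -> None:
    m.to_frame().to_csv(path, index_label="id")


def write_edgelist_csv(m: AssociationMatrix, path) -> None:
    m.to_edgelist().to_csv(path, index=False)
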