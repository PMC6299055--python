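"""Manly-Bejder permutation test for preferred/avoided companionship.

The null model holds each sampling period's group-by-individual incidence
matrix margins fixed (each group keeps its size, each individual its number of
group memberships within the period) and randomises who-was-with-whom through a
Markov chain of 2x2 "checkerboard" swaps.  Swaps are confined to a single
period's matrix, so an individual is never moved across periods.  Higher
observed variation of the association indices (SD, CV) than in the permuted
data indicates preferred and avoided companions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import dyad_counts, hwi
from .records_io import PeriodMatrices


class DegenerateDataError(ValueError):
    """All dyads have identical indices; margin-preserving swaps cannot vary them."""


@dataclass
class PermutationResult:
    """Observed statistics, permutation null distributions, and p-values.

    ``p_value[stat]`` is the one-sided (greater) proportion of saved
    permutations with a null statistic >= the observed one; ``p_two_sided``
    doubles the smaller tail (capped at 1).  ``p_trace[stat][k]`` is the
    one-sided p after k+1 saved permutations, for convergence diagnostics.
    """

    observed: dict[str, float]
    null_distribution: dict[str, np.ndarray]
    p_value: dict[str, float]
    p_less: dict[str, float]
    p_two_sided: dict[str, float]
    p_trace: dict[str, np.ndarray]
    n_permutations: int
    flips_between_saves: int
    burn_in: int
    seed: int | None
    n_failed_flips: int = 0

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "p_less": self.p_less,
            "p_two_sided": self.p_two_sided,
            "null_mean": {k: float(v.mean()) for k, v in self.null_distribution.items()},
            "null_sd": {k: float(v.std(ddof=1)) for k, v in self.null_distribution.items()},
            "n_permutations": self.n_permutations,
            "flips_between_saves": self.flips_between_saves,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "n_failed_flips": self.n_failed_flips,
        }


def _try_flip(mats: list[np.ndarray], rng: np.random.Generator,
              cum_weights: np.ndarray, eligible: np.ndarray,
              max_tries: int = 50) -> tuple[int, int, int, int, int] | None:
    """Propose one checkerboard swap; return (period, r1, r2, c1, c2) or None.

    A period with >= 2 groups is sampled with probability proportional to its
    matrix size, two of its groups are drawn uniformly, then one column is
    drawn from each discordant set (present in the first group only / in the
    second only).  Swapping moves one column from each set to the other while
    preserving both set sizes, so the proposal is symmetric and the chain's
    stationary distribution is uniform over matrices with the observed margins.
    Returns None (chain stays in place) if a draw finds no discordant columns.
    """
    for _ in range(max_tries):
        p = int(eligible[np.searchsorted(cum_weights, rng.random(), side="right")])
        m = mats[p]
        g = m.shape[0]
        r1 = int(rng.integers(g))
        r2 = int(rng.integers(g - 1))
        if r2 >= r1:
            r2 += 1
        diff = m[r1] != m[r2]
        d1 = np.flatnonzero(diff & (m[r1] == 1))
        d2 = np.flatnonzero(diff & (m[r2] == 1))
        if len(d1) and len(d2):
            c1 = int(d1[rng.integers(len(d1))])
            c2 = int(d2[rng.integers(len(d2))])
            return p, r1, r2, c1, c2
    return None


def _apply_flip(m: np.ndarray, r1: int, r2: int, c1: int, c2: int) -> None:
    m[r1, c1] ^= 1
    m[r1, c2] ^= 1
    m[r2, c1] ^= 1
    m[r2, c2] ^= 1


def has_flippable(mats: list[np.ndarray]) -> bool:
    """Exhaustively check whether any period holds a checkerboard submatrix."""
    for m in mats:
        g, n = m.shape
        for r1 in range(g):
            for r2 in range(r1 + 1, g):
                diff = m[r1] != m[r2]
                if (diff & (m[r1] == 1)).any() and (diff & (m[r2] == 1)).any():
                    return True
    return False


def checkerboard_flip(pm: PeriodMatrices, rng) -> tuple[PeriodMatrices, bool]:
    """Perform one margin-preserving 2x2 swap; returns (new matrices, flipped?).

    If no flippable submatrix exists anywhere, the input is returned unchanged
    with ``flipped = False``.
    """
    rng = np.random.default_rng(rng)
    out = pm.copy()
    sampler = _flip_sampler(out.matrices)
    if sampler is None:
        return out, False
    cum_weights, eligible = sampler
    move = _try_flip(out.matrices, rng, cum_weights, eligible)
    if move is None:
        if not has_flippable(out.matrices):
            return out, False
        while move is None:  # flippable exists but sampling missed it
            move = _try_flip(out.matrices, rng, cum_weights, eligible)
    p, r1, r2, c1, c2 = move
    _apply_flip(out.matrices[p], r1, r2, c1, c2)
    return out, True


def _flip_sampler(mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray] | None:
    """Cumulative size weights over periods with >= 2 groups (None if none)."""
    eligible = np.array([i for i, m in enumerate(mats)
                         if m.shape[0] >= 2 and m.shape[1] >= 2], dtype=int)
    if len(eligible) == 0:
        return None
    sizes = np.array([mats[i].size for i in eligible], dtype=float)
    cum = np.cumsum(sizes / sizes.sum())
    cum[-1] = 1.0 + 1e-12
    return cum, eligible


class _ChainState:
    """Incremental x-count bookkeeping for the flip chain.

    The half-weight denominator depends only on per-period identification
    margins, which every flip preserves, so only the joint-association counts
    ``x`` need updating.  A flip in period p touching individuals (c1, c2)
    changes at most those two individuals' association rows in that period.
    """

    def __init__(self, pm: PeriodMatrices):
        self.mats = [m.copy() for m in pm.matrices]
        self.assoc = pm.association_matrices()
        counts = dyad_counts(pm)
        self.x = counts.x.astype(np.int64)
        self.denominator = counts.denominator

    def _assoc_row(self, p: int, c: int) -> np.ndarray:
        m = self.mats[p]
        in_groups = m[:, c].astype(bool)
        row = m[in_groups].any(axis=0) if in_groups.any() else np.zeros(m.shape[1], bool)
        row[c] = False
        return row

    def flip(self, p: int, r1: int, r2: int, c1: int, c2: int) -> None:
        _apply_flip(self.mats[p], r1, r2, c1, c2)
        a = self.assoc[p]
        for c in (c1, c2):
            new = self._assoc_row(p, c)
            delta = new.astype(np.int8) - a[c].astype(np.int8)
            self.x[c, :] += delta
            self.x[:, c] += delta
            a[c, :] = new
            a[:, c] = new
        # the (c1, c2) entry was corrected twice through the symmetric updates;
        # rebuild it exactly from the final association state
        # (handled naturally: after the c1 update, a[c2, c1] is already new, so
        # the c2 delta at c1 is zero — no double counting occurs.)

    def hwi_triu(self) -> np.ndarray:
        n = self.x.shape[0]
        iu = np.triu_indices(n, k=1)
        d = self.denominator[iu]
        x = self.x[iu].astype(float)
        return np.divide(x, d, out=np.zeros_like(x), where=d > 0)


def _stats(vals: np.ndarray) -> dict[str, float]:
    sd = float(vals.std(ddof=1))
    mean = float(vals.mean())
    return {"sd": sd, "cv": sd / mean if mean > 0 else float("nan")}


def permutation_test(pm: PeriodMatrices, n_perm: int = 20_000,
                     flips_between_saves: int = 100, burn_in: int = 1000,
                     seed: int | None = None) -> PermutationResult:
    """Markov-chain permutation test on the SD and CV of the half-weight index.

    Every ``flips_between_saves`` successful swaps the index matrix is
    recomputed (incrementally) and its SD and CV over dyads recorded.  One-sided
    p-values (greater) answer the directional question — is dyadic variation
    higher than expected under random within-period association?
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    state = _ChainState(pm)
    observed_vals = state.hwi_triu()
    if np.allclose(observed_vals, observed_vals[0]):
        raise DegenerateDataError(
            "all dyadic indices are identical (e.g. everyone always together); "
            "margin-preserving permutations cannot produce a null distribution")
    observed = _stats(observed_vals)

    sampler = _flip_sampler(state.mats)
    if sampler is None or not has_flippable(state.mats):
        raise DegenerateDataError("no checkerboard submatrix exists in any period")
    cum_weights, eligible = sampler

    n_failed = 0

    def do_flips(k: int) -> None:
        nonlocal n_failed
        done = 0
        while done < k:
            move = _try_flip(state.mats, rng, cum_weights, eligible)
            if move is None:
                n_failed += 1
                if n_failed > 50 and not has_flippable(state.mats):
                    return
                continue
            state.flip(*move)
            done += 1

    do_flips(burn_in)
    null = {"sd": np.empty(n_perm), "cv": np.empty(n_perm)}
    for i in range(n_perm):
        do_flips(flips_between_saves)
        s = _stats(state.hwi_triu())
        null["sd"][i] = s["sd"]
        null["cv"][i] = s["cv"]

    k = np.arange(1, n_perm + 1)
    p_value, p_less, p_two, trace = {}, {}, {}, {}
    for stat in ("sd", "cv"):
        ge = null[stat] >= observed[stat]
        le = null[stat] <= observed[stat]
        p_value[stat] = float(ge.mean())
        p_less[stat] = float(le.mean())
        p_two[stat] = float(min(1.0, 2.0 * min(p_value[stat], p_less[stat])))
        trace[stat] = np.cumsum(ge) / k
    return PermutationResult(
        observed=observed, null_distribution=null, p_value=p_value,
        p_less=p_less, p_two_sided=p_two, p_trace=trace,
        n_permutations=n_perm, flips_between_saves=flips_between_saves,
        burn_in=burn_in, seed=seed, n_failed_flips=n_failed)
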