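"""Standardised lagged association rates (SLAR) and social-dynamics models.

The SLAR g'(tau) estimates the probability that a randomly chosen current
associate of an individual is a specific associate from tau days earlier,
standardised for incomplete identification.  For permanent groups of constant
size g with full identification it plateaus at exactly 1/(g-1).  Four
exponential social-organisation models are fitted to the binned rates by
binomial quasi-likelihood and compared by QAIC:

    CC      g'(tau) = a                       (constant companions)
    CA      g'(tau) = a * exp(-b tau)         (casual acquaintances)
    CC+CA   g'(tau) = a + c * exp(-b tau)
    2CA     g'(tau) = a * exp(-b tau) + c * exp(-d tau)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .records_io import PeriodMatrices

MODEL_NAMES = ("CC", "CA", "CC+CA", "2CA")
_MODEL_K = {"CC": 1, "CA": 2, "CC+CA": 3, "2CA": 4}


@dataclass
class SLARCurve:
    """Binned lagged association rates with jackknife SEs and a null rate.

    ``bins`` has columns tau (denominator-weighted mean lag, days), g
    (estimate), se, num, den, null.  ``window_edges`` are the lag boundaries of
    the moving-average windows, reused by the jackknife and the null so all
    three are computed on identical binning.
    """

    bins: pd.DataFrame
    moving_average_size: int
    window_edges: list[tuple[float, float]]

    def to_csv(self, path) -> None:
        self.bins.to_csv(path, index=False)


@dataclass
class SocialModelFit:
    """One fitted social-organisation model with its QAIC bookkeeping."""

    model: str
    params: dict[str, float]
    log_likelihood: float
    k: int
    c_hat: float
    qaic: float
    delta_qaic: float = math.nan
    converged: bool = True

    @property
    def formula(self) -> str:
        p = self.params
        if self.model == "CC":
            return f"{p['a']:.6g}"
        if self.model == "CA":
            return f"{p['a']:.6g}*exp(-{p['b']:.6g}*tau)"
        if self.model == "CC+CA":
            return f"{p['a']:.6g} + {p['c']:.6g}*exp(-{p['b']:.6g}*tau)"
        return (f"{p['a']:.6g}*exp(-{p['b']:.6g}*tau) + "
                f"{p['c']:.6g}*exp(-{p['d']:.6g}*tau)")

    def to_dict(self) -> dict:
        return {"model": self.model, "formula": self.formula, "params": self.params,
                "log_likelihood": self.log_likelihood, "k": self.k,
                "c_hat": self.c_hat, "qaic": self.qaic,
                "delta_qaic": self.delta_qaic, "converged": self.converged}


def evaluate_model(model: str, params: dict[str, float], tau) -> np.ndarray:
    """Evaluate a social-organisation model at lags ``tau`` (days)."""
    tau = np.asarray(tau, dtype=float)
    a = params.get("a", 0.0)
    b = params.get("b", 0.0)
    c = params.get("c", 0.0)
    d = params.get("d", 0.0)
    if model == "CC":
        return np.full_like(tau, a)
    if model == "CA":
        return a * np.exp(-b * tau)
    if model == "CC+CA":
        return a + c * np.exp(-b * tau)
    if model == "2CA":
        return a * np.exp(-b * tau) + c * np.exp(-d * tau)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

def _pair_terms(pm: PeriodMatrices) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                             np.ndarray, np.ndarray]:
    """Per ordered period pair (j earlier, k later): lag, numerator, denominator.

    numerator_jk = number of (individual, partner) pairs associated in both
    periods; denominator_jk = sum over individuals of (associates in j) x
    (associates in k) — the standardisation by the later period's identified
    associates.  Also returns the period indices (j, k) of each term for
    jackknife masking.
    """
    assoc = pm.association_matrices()
    rowsums = [a.sum(axis=1).astype(float) for a in assoc]
    mids = pm.midpoints
    P = pm.n_periods
    lags, nums, dens, js, ks = [], [], [], [], []
    for j in range(P):
        aj, rj = assoc[j], rowsums[j]
        for k in range(j + 1, P):
            den = float(rj @ rowsums[k])
            if den == 0:
                continue
            num = float(np.logical_and(aj, assoc[k]).sum())
            lags.append(mids[k] - mids[j])
            nums.append(num)
            dens.append(den)
            js.append(j)
            ks.append(k)
    return (np.asarray(lags), np.asarray(nums), np.asarray(dens),
            np.asarray(js, dtype=int), np.asarray(ks, dtype=int))


def _make_windows(lags: np.ndarray, dens: np.ndarray,
                  moving_average_size: int) -> list[tuple[float, float]]:
    """Greedy non-overlapping lag windows accumulating >= the target denominator.

    Accumulation runs over distinct lags (all terms at one lag stay in one
    window, so windows are clean lag intervals).  A trailing partial window is
    merged into the last full one so every bin carries comparable weight.
    """
    uniq = np.unique(lags)
    per_lag = {u: 0.0 for u in uniq}
    for lag, den in zip(lags, dens):
        per_lag[lag] += den
    edges: list[tuple[float, float]] = []
    acc = 0.0
    start = uniq[0]
    last = start
    for u in uniq:
        acc += per_lag[u]
        last = u
        if acc >= moving_average_size:
            edges.append((float(start), float(last)))
            acc = 0.0
            start = np.nextafter(last, np.inf)
    if acc > 0:
        if edges:
            s, _ = edges[-1]
            edges[-1] = (s, float(last))
        else:
            edges.append((float(start), float(last)))
    return edges


def _aggregate(lags, nums, dens, edges, mask=None) -> pd.DataFrame:
    if mask is None:
        mask = np.ones_like(lags, dtype=bool)
    rows = []
    for lo, hi in edges:
        sel = mask & (lags >= lo) & (lags <= hi)
        den = dens[sel].sum()
        num = nums[sel].sum()
        tau = float((lags[sel] * dens[sel]).sum() / den) if den > 0 else math.nan
        rows.append({"tau": tau, "g": num / den if den > 0 else math.nan,
                     "num": num, "den": den})
    return pd.DataFrame(rows)


def slar(pm: PeriodMatrices, moving_average_size: int = 8000) -> SLARCurve:
    """Standardised lagged association rate with moving-average smoothing.

    Ordered period-pair contributions are sorted by lag and pooled into
    non-overlapping windows whose denominators total roughly
    ``moving_average_size`` associations; each window's rate is plotted at its
    denominator-weighted mean lag.
    """
    if pm.n_periods < 2:
        raise ValueError("need at least two sampling periods")
    lags, nums, dens, _, _ = _pair_terms(pm)
    if len(lags) == 0 or dens.sum() == 0:
        warnings.warn("all lagged denominators are zero; empty curve",
                      RuntimeWarning, stacklevel=2)
        empty = pd.DataFrame(columns=["tau", "g", "num", "den", "se", "null"])
        return SLARCurve(bins=empty, moving_average_size=moving_average_size,
                         window_edges=[])
    edges = _make_windows(lags, dens, moving_average_size)
    bins = _aggregate(lags, nums, dens, edges)
    bins["se"] = np.nan
    bins["null"] = np.nan
    return SLARCurve(bins=bins, moving_average_size=moving_average_size,
                     window_edges=edges)


def jackknife_se(pm: PeriodMatrices, curve: SLARCurve) -> SLARCurve:
    """Temporal jackknife SEs: omit one sampling period at a time.

    Replicate curves reuse the full curve's lag windows.  SE per bin is
    sqrt(((n-1)/n) * sum_i (g_(i) - mean g_(i))^2) over the n replicates in
    which the bin retains a positive denominator; bins missing from any
    replicate are flagged in the ``se_incomplete`` column.
    """
    if pm.n_periods < 3:
        raise ValueError("jackknife needs at least three periods")
    lags, nums, dens, js, ks = _pair_terms(pm)
    edges = curve.window_edges
    reps = []
    for omit in range(pm.n_periods):
        mask = (js != omit) & (ks != omit)
        reps.append(_aggregate(lags, nums, dens, edges, mask)["g"].to_numpy())
    reps = np.array(reps)  # (n_periods, n_bins)
    se = np.full(reps.shape[1], np.nan)
    incomplete = np.zeros(reps.shape[1], dtype=bool)
    for b in range(reps.shape[1]):
        col = reps[:, b]
        ok = ~np.isnan(col)
        incomplete[b] = not ok.all()
        n = ok.sum()
        if n >= 2:
            g = col[ok]
            se[b] = math.sqrt((n - 1) / n * float(((g - g.mean()) ** 2).sum()))
    bins = curve.bins.copy()
    bins["se"] = se
    bins["se_incomplete"] = incomplete
    return SLARCurve(bins=bins, moving_average_size=curve.moving_average_size,
                     window_edges=edges)


def null_rate(pm: PeriodMatrices, curve: SLARCurve, n_randomizations: int = 20,
              seed: int | None = None) -> SLARCurve:
    """Expected SLAR under random association.

    Identities are permuted uniformly within each period (preserving group
    sizes and per-period identification counts), the rate recomputed on the
    curve's lag windows, and averaged over randomisations.  In the limit of all
    groups of size 2 with uniform detection over N individuals the null
    approaches 1/(N-1).
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    rng = np.random.default_rng(seed)
    edges = curve.window_edges
    acc = np.zeros(len(edges))
    n_ind = pm.n_individuals
    for _ in range(n_randomizations):
        shuffled = pm.copy()
        shuffled.matrices = [m[:, rng.permutation(n_ind)] for m in pm.matrices]
        lags, nums, dens, _, _ = _pair_terms(shuffled)
        g = _aggregate(lags, nums, dens, edges)["g"].to_numpy()
        acc += np.nan_to_num(g, nan=0.0)
    bins = curve.bins.copy()
    bins["null"] = acc / n_randomizations
    return SLARCurve(bins=bins, moving_average_size=curve.moving_average_size,
                     window_edges=edges)


# ---------------------------------------------------------------------------
# Model fitting and QAIC selection
# ---------------------------------------------------------------------------

_EPS = 1e-10


def _binom_loglik(model: str, params: dict, tau, num, den) -> float:
    p = np.clip(evaluate_model(model, params, tau), _EPS, 1 - _EPS)
    return float((num * np.log(p) + (den - num) * np.log1p(-p)).sum())


def _param_names(model: str) -> list[str]:
    return {"CC": ["a"], "CA": ["a", "b"], "CC+CA": ["a", "c", "b"],
            "2CA": ["a", "b", "c", "d"]}[model]


def _fit_one(model: str, tau, num, den) -> tuple[dict, float, bool]:
    names = _param_names(model)
    gbar = float(num.sum() / den.sum())
    gmax = float(np.clip((num / den).max(initial=gbar), _EPS, 1.0))
    starts = []
    for b0 in (0.001, 0.05, 0.5):
        s = {"a": gbar, "b": b0, "c": max(gmax - gbar, 0.01), "d": b0 * 10}
        starts.append([s[n] for n in names])
    starts.append([{"a": gmax, "b": 0.01, "c": gbar / 2, "d": 1.0}[n] for n in names])
    bounds = [(0.0, 1.0) if n in ("a", "c") else (0.0, 50.0) for n in names]

    def nll(vec):
        return -_binom_loglik(model, dict(zip(names, vec)), tau, num, den)

    best, best_val = None, np.inf
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val:
            best, best_val = res, res.fun
    converged = bool(best is not None and np.isfinite(best_val))
    params = dict(zip(names, [float(v) for v in best.x]))
    return params, -best_val, converged


def overdispersion(fit: SocialModelFit, tau, num, den) -> float:
    """Pearson chi-square per degree of freedom of a fitted model, floored at 1."""
    tau, num, den = map(np.asarray, (tau, num, den))
    p = np.clip(evaluate_model(fit.model, fit.params, tau), _EPS, 1 - _EPS)
    chi2 = float((((num - den * p) ** 2) / (den * p * (1 - p))).sum())
    df = len(tau) - fit.k
    if df <= 0:
        return 1.0
    return max(1.0, chi2 / df)


def fit_models(curve_or_bins, models: tuple[str, ...] = MODEL_NAMES) -> list[SocialModelFit]:
    """Fit social-organisation models to binned rates and rank them by QAIC.

    Per bin, numerator ~ Binomial(denominator, model(tau)).  The overdispersion
    scale c_hat is the Pearson chi-square/df of the most general model (2CA),
    floored at 1, and shared across models: QAIC = -2 logL / c_hat + 2K.
    Non-converged fits are flagged and excluded from the delta ranking.
    """
    bins = curve_or_bins.bins if isinstance(curve_or_bins, SLARCurve) else curve_or_bins
    bins = bins.dropna(subset=["tau", "g"])
    if len(bins) < 2:
        raise ValueError("need at least two bins to fit models")
    tau = bins["tau"].to_numpy(float)
    num = bins["num"].to_numpy(float)
    den = bins["den"].to_numpy(float)

    ref_params, ref_ll, ref_ok = _fit_one("2CA", tau, num, den)
    ref = SocialModelFit(model="2CA", params=ref_params, log_likelihood=ref_ll,
                         k=4, c_hat=1.0, qaic=math.nan, converged=ref_ok)
    c_hat = overdispersion(ref, tau, num, den) if ref_ok else 1.0

    fits = []
    for name in models:
        if name == "2CA":
            params, ll, ok = ref_params, ref_ll, ref_ok
        else:
            params, ll, ok = _fit_one(name, tau, num, den)
        k = _MODEL_K[name]
        qaic = -2.0 * ll / c_hat + 2 * k
        fits.append(SocialModelFit(model=name, params=params, log_likelihood=ll,
                                   k=k, c_hat=c_hat, qaic=qaic, converged=ok))
    ok_fits = [f for f in fits if f.converged]
    if not ok_fits:
        warnings.warn("no model converged", RuntimeWarning, stacklevel=2)
        return fits
    qmin = min(f.qaic for f in ok_fits)
    for f in fits:
        f.delta_qaic = f.qaic - qmin if f.converged else math.nan
    return fits


def best_model(fits: list[SocialModelFit]) -> SocialModelFit:
    ok = [f for f in fits if f.converged]
    return min(ok, key=lambda f: f.qaic)
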