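"""Standard figures: SLAR curve with fitted model and null, diel bar chart,
and per-individual fishery-interaction proportions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .popstats import DielTable, FisheryReport
from .slar import SLARCurve, SocialModelFit, evaluate_model


def plot_slar(curve: SLARCurve, fit: SocialModelFit | None, path) -> None:
    """Lagged rate estimates +/- SE, best-fit model dotted, null rate dashed."""
    bins = curve.bins.dropna(subset=["tau", "g"])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(bins["tau"], bins["g"], yerr=bins.get("se"), fmt="o-",
                capsize=3, label="SLAR")
    if fit is not None and len(bins):
        tau = np.geomspace(max(bins["tau"].min(), 1e-3), bins["tau"].max(), 200)
        ax.plot(tau, evaluate_model(fit.model, fit.params, tau), ":",
                label=f"best fit ({fit.model})")
    if "null" in bins and bins["null"].notna().any():
        ax.plot(bins["tau"], bins["null"], "--", label="null rate")
    ax.set_xscale("log")
    ax.set_xlabel("time lag (days)")
    ax.set_ylabel("standardised lagged association rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_diel(table: DielTable, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    table.counts.plot.bar(ax=ax)
    ax.set_ylabel("encounters")
    ax.set_title(f"diel occurrence ({table.scope} area), "
                 f"Fisher p = {table.fisher_p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fishery(report: FisheryReport, path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    sub = report.per_individual.sort_values("proportion", ascending=False)
    ax.bar(sub["individual_id"], sub["proportion"])
    ax.set_ylabel("share of all trawler interactions")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
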