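"""Config-driven orchestration of the full analysis.

``run_pipeline`` chains restriction -> period matrices -> association indices
-> permutation test -> SLAR + model fits -> clustering + CCC -> network
metrics -> population statistics, writes every stage's artefacts into the
output directory, and collects the headline numbers into ``summary.json``.  A
single seed is fanned out to per-stage child seeds so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, metrics, permutation, plots, popstats, records_io
from . import structure, synthetic
from .slar import (best_model, fit_models, jackknife_se, null_rate,
                   slar as slar_curve)

log = logging.getLogger("podnet")


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs from earlier stages are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Either ``input_paths`` (mapping with encounters/memberships/individuals
    CSVs) or ``preset`` (simulation scenario name or YAML path) must be given.
    Heavy defaults (20,000 permutations, 10,000 bootstraps) mirror the study
    conditions; scale them down explicitly for quick runs.
    """

    output_dir: str = "podnet_out"
    input_paths: dict | None = None
    preset: str | None = None
    seed: int | None = None
    min_occasions: int = 4
    min_years: int = 2
    period_length_days: int = 1
    extra_permutation_period_lengths: tuple[int, ...] = ()
    index_flavor: str = "HWI"
    n_permutations: int = 20_000
    flips_between_saves: int = 100
    permutation_burn_in: int = 1000
    moving_average_size: int = 8000
    n_null_randomizations: int = 20
    n_bootstrap: int = 10_000
    n_mantel_permutations: int = 10_000
    clustering_method: str = "eigenvector"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "extra_permutation_period_lengths" in data:
            data["extra_permutation_period_lengths"] = tuple(
                data["extra_permutation_period_lengths"])
        return cls(**data)


def _child_seeds(seed: int | None, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


def _stage(name: str, timings: dict):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s ...", name)
            self.t0 = time.perf_counter()

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                raise PipelineStageError(name, exc) from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, [
        "simulate", "permutation", "null_rate", "bootstrap", "mantel"])
    timings: dict[str, float] = {}
    summary: dict = {"seed": config.seed, "child_seeds": seeds}

    truth = None
    with _stage("input", timings):
        if config.input_paths:
            paths = config.input_paths
            for key in ("encounters", "memberships", "individuals"):
                if key not in paths or not Path(paths[key]).exists():
                    raise FileNotFoundError(f"missing input file for {key!r}")
            table = records_io.read_encounters(paths["encounters"],
                                               paths["memberships"],
                                               paths["individuals"])
        elif config.preset:
            cfg = synthetic.load_preset(config.preset)
            cfg = dataclasses.replace(cfg, seed=seeds["simulate"])
            table, truth = synthetic.simulate(cfg)
            records_io.write_encounters(table, out / "encounters.csv",
                                        out / "memberships.csv",
                                        out / "individuals.csv")
            truth.to_json(out / "ground_truth.json")
        else:
            raise ValueError("config needs input_paths or preset")

    with _stage("restrict", timings):
        restricted, retained = records_io.apply_restrictions(
            table, config.min_occasions, config.min_years)
        summary["restriction"] = records_io.restriction_summary(restricted)
        records_io.write_encounters(restricted, out / "restricted_encounters.csv",
                                    out / "restricted_memberships.csv",
                                    out / "restricted_individuals.csv")

    with _stage("matrices", timings):
        pm = records_io.build_period_matrices(restricted, config.period_length_days)

    with _stage("indices", timings):
        counts = association.dyad_counts(pm)
        m_hwi = association.hwi(counts)
        m_hwig = association.hwig(m_hwi)
        m = m_hwig if config.index_flavor == "HWIG" else m_hwi
        association.write_matrix_csv(m_hwi, out / "hwi_matrix.csv")
        association.write_matrix_csv(m_hwig, out / "hwig_matrix.csv")
        association.write_edgelist_csv(m_hwi, out / "hwi_edges.csv")

    with _stage("permutation", timings):
        perm = permutation.permutation_test(
            pm, n_perm=config.n_permutations,
            flips_between_saves=config.flips_between_saves,
            burn_in=config.permutation_burn_in, seed=seeds["permutation"])
        summary["permutation"] = perm.to_dict()
        (out / "permutation.json").write_text(json.dumps(perm.to_dict(), indent=1))
        extra = {}
        for plen in config.extra_permutation_period_lengths:
            pm_alt = records_io.build_period_matrices(restricted, plen)
            p_alt = permutation.permutation_test(
                pm_alt, n_perm=config.n_permutations,
                flips_between_saves=config.flips_between_saves,
                burn_in=config.permutation_burn_in, seed=seeds["permutation"])
            extra[str(plen)] = p_alt.to_dict()
        if extra:
            summary["permutation_extra_periods"] = extra

    with _stage("slar", timings):
        curve = slar_curve(pm, config.moving_average_size)
        curve = jackknife_se(pm, curve)
        curve = null_rate(pm, curve, config.n_null_randomizations,
                          seed=seeds["null_rate"])
        fits = fit_models(curve)
        best = best_model(fits)
        curve.to_csv(out / "slar_curve.csv")
        (out / "slar_models.json").write_text(
            json.dumps([f.to_dict() for f in fits], indent=1))
        plots.plot_slar(curve, best, out / "slar.png")
        summary["slar"] = {"n_bins": int(len(curve.bins)),
                           "best_model": best.model,
                           "models": [f.to_dict() for f in fits]}

    with _stage("clustering", timings):
        dend = structure.average_linkage(m)
        (out / "dendrogram.nwk").write_text(dend.to_newick())
        if config.clustering_method == "dendrogram_cut":
            assign = structure.best_dendrogram_cut(dend, m)
        else:
            assign = structure.eigenvector_communities(m)
        cut = structure.best_dendrogram_cut(dend, m)
        q_greg = structure.modularity(m_hwi, assign.labels,
                                      gregariousness_corrected=True)
        with (out / "cluster_labels.csv").open("w") as fh:
            fh.write("individual_id,cluster\n")
            for i in sorted(assign.labels):
                fh.write(f"{i},{assign.labels[i]}\n")
        with (out / "modularity_curve.csv").open("w") as fh:
            fh.write("cut_index,modularity\n")
            for t, q in cut.modularity_curve:
                fh.write(f"{t:.6f},{q:.6f}\n")
        summary["clustering"] = {
            "method": assign.method, "n_clusters": assign.n_clusters,
            "cluster_sizes": {str(k): v for k, v in
                              sorted(assign.cluster_sizes().items())},
            "modularity_q": assign.modularity_q,
            "modularity_q_gregariousness": q_greg,
            "cut_index": cut.cut_index, "cut_modularity_q": cut.modularity_q,
            "cut_n_clusters": cut.n_clusters,
            "ccc": dend.ccc,
            "singleton_suggestions": {k: int(v) for k, v in
                                      assign.singleton_suggestions.items()},
        }
        labels = assign.labels

    with _stage("metrics", timings):
        node_table = metrics.node_metrics(m)
        node_table.to_csv(out / "node_metrics.csv")
        summary_table = metrics.cluster_summary(node_table, labels)
        summary_table.to_csv(out / "cluster_metrics.csv", index=False)
        metrics.export_graphml(m, out / "network.graphml", labels, node_table)
        metrics.export_graphml(m, out / "network_strong.graphml", labels,
                               node_table,
                               min_index=metrics.twice_mean_threshold(m))
        summary["metrics_by_cluster"] = summary_table.to_dict(orient="records")

    with _stage("popstats", timings):
        diff = popstats.social_differentiation(counts, config.n_bootstrap,
                                               seed=seeds["bootstrap"])
        summary["social_differentiation"] = diff.to_dict()
        mantel = popstats.mantel_class_test(
            m, {i: str(c) for i, c in labels.items()},
            n_perm=config.n_mantel_permutations, seed=seeds["mantel"])
        summary["mantel_clusters"] = mantel.to_dict()
        sex = dict(zip(restricted.registry["individual_id"],
                       restricted.registry["sex"]))
        sexed = {i: s for i, s in sex.items() if s in ("M", "F")}
        if len(set(sexed.values())) == 2:
            mantel_sex = popstats.mantel_class_test(
                m, sexed, n_perm=config.n_mantel_permutations,
                seed=seeds["mantel"])
            summary["mantel_sexes"] = mantel_sex.to_dict()
            summary["sex_class_means"] = association.class_mean_index(
                m, sex).to_dict(orient="records")

        diel = {}
        for scope in ("entire", "core"):
            try:
                dt_table = popstats.diel_partition_test(restricted, labels, scope)
            except ValueError as exc:
                log.warning("diel test (%s) skipped: %s", scope, exc)
                continue
            dt_table.counts.to_csv(out / f"diel_{scope}.csv")
            plots.plot_diel(dt_table, out / f"diel_{scope}.png")
            diel[scope] = {"fisher_p": dt_table.fisher_p,
                           "tested_clusters": list(dt_table.tested_clusters),
                           "table": dt_table.fisher_table,
                           "counts": dt_table.counts.to_dict(orient="index")}
        summary["diel"] = diel
        summary["sex_composition"] = popstats.sex_composition(restricted).to_dict()
        fishery = popstats.fishery_interaction_summary(restricted, labels)
        fishery.per_individual.to_csv(out / "fishery_individuals.csv", index=False)
        fishery.per_cluster.to_csv(out / "fishery_clusters.csv", index=False)
        if fishery.n_interactions:
            plots.plot_fishery(fishery, out / "fishery.png")
        summary["fishery"] = {
            "n_interactions": fishery.n_interactions,
            "gear_counts": fishery.gear_counts,
            "pct_pair": fishery.gear_pct("pair"),
            "pct_bottom": fishery.gear_pct("bottom"),
            "per_cluster": fishery.per_cluster.to_dict(orient="records"),
            "max_individual_proportion":
                float(fishery.per_individual["proportion"].max())
                if len(fishery.per_individual) else 0.0,
        }

    if truth is not None:
        with _stage("recovery", timings):
            summary["recovery"] = synthetic.recovery_report(
                truth, labels=labels,
                s_estimate=summary["social_differentiation"]["S"],
                permutation_rejected=summary["permutation"]["p_value"]["sd"] < 0.05,
                selected_model=summary["slar"]["best_model"])

    summary["timings_s"] = timings
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
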