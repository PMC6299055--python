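"""Shared fixtures: hand-built encounter tables and one reusable simulated society."""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from podnet import (EncounterTable, apply_restrictions, build_period_matrices,
                    dyad_counts, hwi, load_preset, simulate)
from podnet.records_io import PeriodMatrices


def build_table(rows, registry=None):
    """Construct an EncounterTable from simple row dicts.

    Each row: {date: 'YYYY-MM-DD', members: [...], time: 'HH:MM', area, trawler}.
    Registry defaults to all seen individuals, unknown sex, not calves.
    """
    enc_rows, mem_rows = [], []
    for k, row in enumerate(rows):
        eid = row.get("id", f"E{k + 1:03d}")
        enc_rows.append({
            "encounter_id": eid,
            "date": dt.date.fromisoformat(row["date"]),
            "time_start": dt.time(*map(int, row.get("time", "08:00").split(":"))),
            "area": row.get("area", "core"),
            "trawler": row.get("trawler", "none"),
        })
        for m in row["members"]:
            mem_rows.append({"encounter_id": eid, "individual_id": m})
    if registry is None:
        ids = sorted({m["individual_id"] for m in mem_rows})
        registry = [{"individual_id": i, "sex": "U", "is_calf": False} for i in ids]
    return EncounterTable(encounters=pd.DataFrame(enc_rows),
                         memberships=pd.DataFrame(mem_rows),
                         registry=pd.DataFrame(registry)).validate()


def pm_from_matrices(mats, ids=None, period_length=1):
    """PeriodMatrices directly from binary arrays (one per period)."""
    mats = [np.asarray(m, dtype=np.uint8) for m in mats]
    n = mats[0].shape[1]
    ids = ids or [f"I{k:02d}" for k in range(n)]
    starts = [dt.date(2020, 1, 1) + dt.timedelta(days=p * period_length)
              for p in range(len(mats))]
    return PeriodMatrices(ids=list(ids), period_starts=starts,
                          period_length_days=period_length, matrices=mats)


def hwi_oracle(pm):
    """Independent per-period double-loop half-weight index computation."""
    n = pm.n_individuals
    x = np.zeros((n, n))
    na = np.zeros(n)
    both = np.zeros((n, n))
    for m in pm.matrices:
        seen = [bool(m[:, i].any()) for i in range(n)]
        for i in range(n):
            if seen[i]:
                na[i] += 1
            for j in range(n):
                if i == j:
                    continue
                if seen[i] and seen[j]:
                    both[i, j] += 1
                    together = any(m[g, i] and m[g, j] for g in range(m.shape[0]))
                    if together:
                        x[i, j] += 1
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            yab = both[i, j] - x[i, j]
            ya = na[i] - both[i, j]
            yb = na[j] - both[i, j]
            d = x[i, j] + yab + (ya + yb) / 2
            out[i, j] = x[i, j] / d if d > 0 else 0.0
    return out


def random_pm(rng, n_ind=8, n_periods=6, max_groups=3):
    """Random small period structure where every individual is seen at least once."""
    while True:
        mats = []
        for _ in range(n_periods):
            g = rng.integers(1, max_groups + 1)
            m = (rng.random((g, n_ind)) < 0.4).astype(np.uint8)
            m = m[m.sum(axis=1) > 0]
            if len(m) == 0:
                m = np.zeros((1, n_ind), dtype=np.uint8)
                m[0, rng.integers(n_ind)] = 1
            mats.append(m)
        pm = pm_from_matrices(mats)
        if np.vstack([m.any(axis=0) for m in mats]).any(axis=0).all():
            return pm


@pytest.fixture(scope="session")
def paper_society():
    """One simulated paper-like society, restricted, with matrices and HWI."""
    cfg = dataclasses.replace(load_preset("paper_like"), seed=1)
    table, truth = simulate(cfg)
    restricted, retained = apply_restrictions(table)
    pm = build_period_matrices(restricted, 1)
    counts = dyad_counts(pm)
    return {"table": table, "truth": truth, "restricted": restricted,
            "retained": retained, "pm": pm, "counts": counts,
            "hwi": hwi(counts)}
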