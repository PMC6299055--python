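"""Reading, validation, restriction rules and period-matrix construction."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from podnet import (apply_restrictions, build_period_matrices, read_encounters,
                    restriction_summary, write_encounters)
from podnet.records_io import (DuplicateEncounterError, FieldParseError,
                               NoIndividualsRetainedError, UnknownReferenceError)

from conftest import build_table


def test_table_counts():
    t = build_table([
        {"date": "2020-01-01", "members": ["A", "B", "C"]},
        {"date": "2020-01-02", "members": ["A", "D"]},
    ])
    assert t.n_encounters == 2
    assert t.n_memberships == 5
    assert len(t.registry) == 4


def test_csv_round_trip(tmp_path):
    t = build_table([
        {"date": "2020-01-01", "time": "07:30", "members": ["A", "B"],
         "area": "core", "trawler": "pair"},
        {"date": "2021-06-15", "time": "18:05", "members": ["B", "C"],
         "area": "other", "trawler": "none"},
    ])
    paths = [tmp_path / f for f in ("e.csv", "m.csv", "i.csv")]
    write_encounters(t, *paths)
    back = read_encounters(*paths)
    pd.testing.assert_frame_equal(t.encounters, back.encounters)
    pd.testing.assert_frame_equal(t.memberships, back.memberships)
    pd.testing.assert_frame_equal(t.registry, back.registry)


@pytest.mark.parametrize("mutate,error,fragment", [
    (lambda d: d["e"].append("E001,2020-01-01,08:00,core,none"),
     DuplicateEncounterError, "E001"),
    (lambda d: d["m"].append("E001,GHOST"), UnknownReferenceError, "GHOST"),
    (lambda d: d["m"].append("E999,A"), UnknownReferenceError, "E999"),
    (lambda d: d["e"].append("E002,2020-13-01,08:00,core,none"),
     FieldParseError, "date"),
    (lambda d: d["e"].append("E002,2020-01-02,8h00,core,none"),
     FieldParseError, "time"),
])
def test_validation_errors(tmp_path, mutate, error, fragment):
    data = {
        "e": ["encounter_id,date,time_start,area,trawler",
              "E001,2020-01-01,08:00,core,none"],
        "m": ["encounter_id,individual_id", "E001,A"],
        "i": ["individual_id,sex,is_calf", "A,F,0", "GHOSTLESS,U,0"],
    }
    mutate(data)
    paths = {}
    for key in data:
        p = tmp_path / f"{key}.csv"
        p.write_text("\n".join(data[key]) + "\n")
        paths[key] = p
    with pytest.raises(error, match=fragment):
        read_encounters(paths["e"], paths["m"], paths["i"])


def _spread_dates(n, years):
    """n dates cycling through the given years, all distinct days."""
    out = []
    for k in range(n):
        out.append(f"{years[k % len(years)]}-01-{k + 1:02d}")
    return out


def test_restriction_thresholds():
    rows = []
    # KEEP: 4 occasions across 2 years; DROP: 10 occasions in one year;
    # DROP: 3 occasions only; anchor individuals keep encounters alive
    for d in _spread_dates(4, [2020, 2021]):
        rows.append({"date": d, "members": ["KEEP", "ANCHOR"]})
    for k in range(10):
        rows.append({"date": f"2020-02-{k + 1:02d}", "members": ["ONEYEAR", "ANCHOR2"]})
    for d in _spread_dates(3, [2020, 2021]):
        rows.append({"date": d.replace("-01-", "-03-"), "members": ["FEW", "ANCHOR"]})
    for d in _spread_dates(8, [2020, 2021]):
        rows.append({"date": d.replace("-01-", "-04-"), "members": ["ANCHOR", "ANCHOR2"]})
    t = build_table(rows)
    restricted, retained = apply_restrictions(t)
    assert "KEEP" in retained
    assert "ONEYEAR" not in retained  # single-year transient however often seen
    assert "FEW" not in retained
    assert {"ANCHOR", "ANCHOR2"} <= set(retained)


def test_calves_removed():
    rows = [{"date": d, "members": ["MUM", "CALF"]}
            for d in _spread_dates(6, [2020, 2021])]
    reg = [{"individual_id": "MUM", "sex": "F", "is_calf": False},
           {"individual_id": "CALF", "sex": "U", "is_calf": True}]
    restricted, retained = apply_restrictions(build_table(rows, reg))
    assert retained == ["MUM"]
    assert "CALF" not in set(restricted.memberships["individual_id"])


def test_same_day_duplicates_merged_but_distinct_groups_kept():
    base = [{"date": d, "members": ["A", "B"]} for d in _spread_dates(4, [2020, 2021])]
    extra = [
        {"date": "2020-01-01", "time": "10:00", "members": ["A", "B"]},  # duplicate
        {"date": "2020-01-01", "time": "11:00", "members": ["A"]},       # different group
    ]
    t = build_table(base + extra)
    restricted, _ = apply_restrictions(t, min_occasions=2, min_years=2)
    day1 = restricted.encounters[restricted.encounters["date"] == dt.date(2020, 1, 1)]
    # duplicate at 10:00 dropped (earliest kept), singleton {A} group kept
    assert len(day1) == 2
    assert dt.time(8, 0) in set(day1["time_start"])
    assert dt.time(11, 0) in set(day1["time_start"])


def test_restriction_idempotent(paper_society):
    once, ids_once = apply_restrictions(paper_society["table"])
    twice, ids_twice = apply_restrictions(once)
    assert ids_once == ids_twice
    pd.testing.assert_frame_equal(once.encounters.reset_index(drop=True),
                                  twice.encounters.reset_index(drop=True))


def test_no_individuals_retained_raises():
    t = build_table([{"date": "2020-01-01", "members": ["A", "B"]}])
    with pytest.raises(NoIndividualsRetainedError):
        apply_restrictions(t)


def test_restriction_summary_percentages():
    # 38 residents: 32 seen 5 times, 6 seen 4 times, all across two years
    rows = {}
    for i in range(38):
        ind = f"D{i:02d}"
        n = 5 if i < 32 else 4
        for k in range(n):
            day = f"{2020 + k % 2}-{(i % 12) + 1:02d}-{(i + k) % 27 + 1:02d}"
            rows.setdefault((day, k), []).append(ind)
    t = build_table([{"date": d, "members": mem} for (d, _), mem in rows.items()])
    restricted, retained = apply_restrictions(t)
    assert len(retained) == 38
    s = restriction_summary(restricted)
    assert s["pct_seen_5plus"] == pytest.approx(100 * 32 / 38, abs=1e-9)
    assert round(s["pct_seen_5plus"], 1) == 84.2


def test_period_matrices_daily_and_five_day():
    t = build_table([
        {"date": "2020-01-01", "members": ["A", "B"]},
        {"date": "2020-01-02", "members": ["B", "C"]},
        {"date": "2020-01-03", "members": ["A", "C"]},
    ])
    daily = build_period_matrices(t, 1)
    assert daily.n_periods == 3
    assert all(m.shape[0] == 1 for m in daily.matrices)
    five = build_period_matrices(t, 5)
    assert five.n_periods == 1
    assert five.matrices[0].shape == (3, 3)


def test_individual_in_two_groups_one_period():
    t = build_table([
        {"date": "2020-01-01", "time": "08:00", "members": ["A", "B"]},
        {"date": "2020-01-01", "time": "12:00", "members": ["A", "C"]},
    ])
    pm = build_period_matrices(t, 1)
    a_col = pm.ids.index("A")
    assert pm.matrices[0][:, a_col].sum() == 2


def test_period_length_validation(paper_society):
    with pytest.raises(ValueError):
        build_period_matrices(paper_society["restricted"], 0)


def test_column_sums_match_total_sightings(paper_society):
    restricted = paper_society["restricted"]
    pm = paper_society["pm"]
    # every encounter appears in exactly one period, so summed incidence
    # equals each individual's retained sighting count
    totals = sum(m.sum(axis=0) for m in pm.matrices)
    expected = restricted.sightings_per_individual()
    assert np.array_equal(totals, expected[pm.ids].to_numpy())
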