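"""Encounter records: reading, validation, restriction, and sampling-period matrices.

Input data follow the "gambit of the group" convention of photo-identification
surveys: an *encounter* is one observed group of animals on one date; a
*membership* links an identified individual to an encounter; a *registry* carries
per-individual attributes (sex, dependent-calf status).  All downstream analyses
(association indices, permutation tests, lagged rates) operate on binary
group-by-individual incidence matrices built per sampling period, with "day" as
the canonical period.
"""

from __future__ import annotations

import datetime as dt
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_AREAS = frozenset({"core", "other"})
VALID_TRAWLER = frozenset({"none", "pair", "bottom", "both"})
VALID_SEX = frozenset({"F", "M", "U"})


class RecordsError(ValueError):
    """Base class for encounter-record validation failures."""


class DuplicateEncounterError(RecordsError):
    """An encounter id occurs more than once in the encounter file."""


class UnknownReferenceError(RecordsError):
    """A membership row references an encounter or individual that does not exist."""


class FieldParseError(RecordsError):
    """A date, time, or categorical field could not be parsed."""


class NoIndividualsRetainedError(RecordsError):
    """The restriction filter removed every individual."""


@dataclass(frozen=True)
class Individual:
    """One catalogued animal.

    ``sex`` is one of F/M/U (unknown); dependent calves are excluded from all
    association analyses because their sightings are not independent of the
    mother's.
    """

    id: str
    sex: str = "U"
    is_calf: bool = False

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEX:
            raise FieldParseError(f"invalid sex {self.sex!r} for individual {self.id!r}")


@dataclass
class EncounterTable:
    """Tidy encounter / membership / registry records — the single input contract.

    Attributes
    ----------
    encounters : DataFrame with columns
        ``encounter_id`` (str), ``date`` (datetime.date), ``time_start``
        (datetime.time), ``area`` ({core, other}), ``trawler``
        ({none, pair, bottom, both}).
    memberships : DataFrame with columns ``encounter_id``, ``individual_id``.
    registry : DataFrame with columns ``individual_id``, ``sex``, ``is_calf``.
    """

    encounters: pd.DataFrame
    memberships: pd.DataFrame
    registry: pd.DataFrame

    # -- basic introspection ------------------------------------------------
    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    @property
    def n_memberships(self) -> int:
        return len(self.memberships)

    @property
    def individual_ids(self) -> list[str]:
        return sorted(self.registry["individual_id"])

    def members_of(self, encounter_id: str) -> frozenset[str]:
        m = self.memberships
        return frozenset(m.loc[m["encounter_id"] == encounter_id, "individual_id"])

    def sightings_per_individual(self) -> pd.Series:
        """Number of encounters each registry individual appears in (0 for none)."""
        counts = self.memberships.groupby("individual_id").size()
        return counts.reindex(self.individual_ids, fill_value=0)

    def validate(self) -> "EncounterTable":
        """Check referential integrity and field domains; raise on violation."""
        enc = self.encounters
        if enc["encounter_id"].duplicated().any():
            dupes = sorted(enc.loc[enc["encounter_id"].duplicated(), "encounter_id"])
            raise DuplicateEncounterError(f"duplicate encounter id(s): {dupes}")
        bad_area = set(enc["area"]) - VALID_AREAS
        if bad_area:
            raise FieldParseError(f"invalid area value(s): {sorted(bad_area)}")
        bad_trawler = set(enc["trawler"]) - VALID_TRAWLER
        if bad_trawler:
            raise FieldParseError(f"invalid trawler value(s): {sorted(bad_trawler)}")
        if self.registry["individual_id"].duplicated().any():
            d = sorted(self.registry.loc[self.registry["individual_id"].duplicated(),
                                         "individual_id"])
            raise DuplicateEncounterError(f"duplicate individual id(s): {d}")
        bad_sex = set(self.registry["sex"]) - VALID_SEX
        if bad_sex:
            raise FieldParseError(f"invalid sex value(s): {sorted(bad_sex)}")

        known_enc = set(enc["encounter_id"])
        known_ind = set(self.registry["individual_id"])
        mem = self.memberships
        unknown_enc = set(mem["encounter_id"]) - known_enc
        if unknown_enc:
            raise UnknownReferenceError(
                f"membership references unknown encounter id(s): {sorted(unknown_enc)}")
        unknown_ind = set(mem["individual_id"]) - known_ind
        if unknown_ind:
            raise UnknownReferenceError(
                f"membership references unknown individual id(s): {sorted(unknown_ind)}")
        if mem.duplicated(["encounter_id", "individual_id"]).any():
            d = mem[mem.duplicated(["encounter_id", "individual_id"])]
            raise DuplicateEncounterError(
                "individual listed more than once in an encounter: "
                f"{d[['encounter_id', 'individual_id']].values.tolist()}")
        return self


def _parse_date(value: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise FieldParseError(f"row {row}: unparseable date {value!r}") from exc


def _parse_time(value: str, row: int) -> dt.time:
    s = str(value).strip()
    try:
        h, m = s.split(":")
        return dt.time(int(h), int(m))
    except (ValueError, TypeError) as exc:
        raise FieldParseError(f"row {row}: unparseable time {value!r}") from exc


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FieldParseError(f"{path}: missing column(s) {missing}")
    return df


def read_encounters(encounters_csv, memberships_csv, individuals_csv) -> EncounterTable:
    """Read and validate the three-CSV encounter contract.

    Parse errors report the 1-based data row number of the offending record.
    """
    enc = _read_csv(encounters_csv,
                    ["encounter_id", "date", "time_start", "area", "trawler"])
    mem = _read_csv(memberships_csv, ["encounter_id", "individual_id"])
    reg = _read_csv(individuals_csv, ["individual_id", "sex", "is_calf"])

    enc = enc.copy()
    enc["date"] = [_parse_date(v, i + 1) for i, v in enumerate(enc["date"])]
    enc["time_start"] = [_parse_time(v, i + 1) for i, v in enumerate(enc["time_start"])]
    enc["area"] = enc["area"].str.strip()
    enc["trawler"] = enc["trawler"].str.strip()

    reg = reg.copy()
    reg["sex"] = reg["sex"].str.strip()
    try:
        reg["is_calf"] = reg["is_calf"].astype(int).astype(bool)
    except ValueError as exc:
        raise FieldParseError(f"individuals file: unparseable is_calf flag: {exc}") from exc

    table = EncounterTable(encounters=enc.reset_index(drop=True),
                           memberships=mem.reset_index(drop=True),
                           registry=reg.reset_index(drop=True))
    return table.validate()


def write_encounters(table: EncounterTable, encounters_csv, memberships_csv,
                     individuals_csv) -> None:
    """Write the table back to the three-CSV contract (ISO dates, HH:MM times)."""
    enc = table.encounters.copy()
    enc["date"] = [d.isoformat() for d in enc["date"]]
    enc["time_start"] = [t.strftime("%H:%M") for t in enc["time_start"]]
    enc.to_csv(encounters_csv, index=False)
    table.memberships.to_csv(memberships_csv, index=False)
    reg = table.registry.copy()
    reg["is_calf"] = reg["is_calf"].astype(int)
    reg.to_csv(individuals_csv, index=False)


# ---------------------------------------------------------------------------
# Restriction rules
# ---------------------------------------------------------------------------

def apply_restrictions(table: EncounterTable, min_occasions: int = 4,
                       min_years: int = 2) -> tuple[EncounterTable, list[str]]:
    """Apply the resident-subset restriction rules.

    Removes dependent calves; retains only individuals encountered on at least
    ``min_occasions`` occasions *and* in at least ``min_years`` distinct calendar
    years (dropping single-year visitors/transients however often seen);
    deduplicates same-day encounters whose retained membership sets are
    identical (keeping the earliest); drops encounters left without retained
    members.  The filter is iterated to a fixed point so that applying it twice
    equals applying it once.
    """
    reg = table.registry[~table.registry["is_calf"]].reset_index(drop=True)
    keep_ids = set(reg["individual_id"])
    mem = table.memberships[table.memberships["individual_id"].isin(keep_ids)]
    enc = table.encounters

    while True:
        dates = enc.set_index("encounter_id")["date"]
        years = mem["encounter_id"].map(dates).map(lambda d: d.year)
        per_ind = pd.DataFrame({"individual_id": mem["individual_id"], "year": years})
        occ = per_ind.groupby("individual_id").size()
        nyears = per_ind.groupby("individual_id")["year"].nunique()
        retained = set(occ[(occ >= min_occasions) & (nyears >= min_years)].index)

        new_mem = mem[mem["individual_id"].isin(retained)]

        # same-day duplicate groups: identical retained membership sets
        sets = (new_mem.groupby("encounter_id")["individual_id"]
                .agg(frozenset).rename("members"))
        enc_aug = enc.join(sets, on="encounter_id")
        enc_aug = enc_aug[enc_aug["members"].notna()]
        enc_aug = enc_aug.sort_values(["date", "time_start", "encounter_id"])
        dedup = enc_aug.drop_duplicates(["date", "members"], keep="first")
        new_enc = dedup.drop(columns="members").reset_index(drop=True)
        new_mem = new_mem[new_mem["encounter_id"].isin(set(new_enc["encounter_id"]))]

        if (len(new_enc) == len(enc) and len(new_mem) == len(mem)
                and retained == set(mem["individual_id"])):
            break
        enc, mem = new_enc, new_mem.reset_index(drop=True)

    if not retained:
        raise NoIndividualsRetainedError(
            "no individuals retained: every animal fails the "
            f">= {min_occasions} occasions in >= {min_years} years rule")

    out = EncounterTable(
        encounters=enc.reset_index(drop=True),
        memberships=mem.reset_index(drop=True),
        registry=reg[reg["individual_id"].isin(retained)].reset_index(drop=True),
    )
    return out, sorted(retained)


def restriction_summary(table: EncounterTable) -> dict:
    """Sighting-frequency summary of a restricted table.

    Reports the share of individuals seen at least 5 and at least 10 times and
    the mean/SD/range of per-individual sighting counts.
    """
    counts = table.sightings_per_individual()
    n = len(counts)
    return {
        "n_individuals": n,
        "n_encounters": table.n_encounters,
        "pct_seen_5plus": 100.0 * float((counts >= 5).sum()) / n if n else float("nan"),
        "pct_seen_10plus": 100.0 * float((counts >= 10).sum()) / n if n else float("nan"),
        "mean_sightings": float(counts.mean()) if n else float("nan"),
        "sd_sightings": float(counts.std(ddof=1)) if n > 1 else float("nan"),
        "min_sightings": int(counts.min()) if n else 0,
        "max_sightings": int(counts.max()) if n else 0,
    }


# ---------------------------------------------------------------------------
# Sampling-period incidence matrices
# ---------------------------------------------------------------------------

@dataclass
class PeriodMatrices:
    """Per-sampling-period binary group-by-individual incidence.

    ``matrices[p]`` is a (groups x individuals) 0/1 array for period ``p``;
    column order (``ids``) is identical across periods.  Multi-day periods tile
    the calendar from the first observation date.  ``midpoints`` give each
    period's midpoint in days from the first period's start, the lag scale used
    by the lagged-association-rate machinery.
    """

    ids: list[str]
    period_starts: list[dt.date]
    period_length_days: int
    matrices: list[np.ndarray]
    encounter_ids: list[list[str]] = field(default_factory=list)

    @property
    def n_periods(self) -> int:
        return len(self.matrices)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def midpoints(self) -> np.ndarray:
        origin = self.period_starts[0]
        half = (self.period_length_days - 1) / 2.0
        return np.array([(s - origin).days + half for s in self.period_starts])

    def seen(self) -> np.ndarray:
        """(periods x individuals) boolean: identified at least once in period."""
        return np.array([m.any(axis=0) for m in self.matrices])

    def association_matrices(self) -> list[np.ndarray]:
        """Per-period symmetric boolean association (share >= 1 group), zero diagonal."""
        out = []
        for m in self.matrices:
            a = (m.T @ m) > 0
            np.fill_diagonal(a, False)
            out.append(a)
        return out

    def copy(self) -> "PeriodMatrices":
        return replace(self, matrices=[m.copy() for m in self.matrices])


def build_period_matrices(table: EncounterTable, period_length_days: int = 1,
                          ids: Iterable[str] | None = None) -> PeriodMatrices:
    """Assemble one incidence matrix per sampling period.

    Individuals are associated within a period iff they share at least one group
    in it.  ``ids`` defaults to the table registry; encounters with no members
    among ``ids`` are skipped, and individuals never sighted are dropped from the
    matrices entirely (they would otherwise enter null rates as permanent
    absentees).
    """
    if period_length_days < 1:
        raise ValueError("period_length_days must be >= 1")
    id_list = sorted(ids) if ids is not None else table.individual_ids
    sighted = set(table.memberships["individual_id"])
    id_list = [i for i in id_list if i in sighted]
    col = {ind: j for j, ind in enumerate(id_list)}

    enc = table.encounters.sort_values(["date", "time_start", "encounter_id"])
    members = table.memberships.groupby("encounter_id")["individual_id"].agg(list)
    origin = enc["date"].min()

    buckets: dict[int, list[tuple[str, list[str]]]] = {}
    for eid, date in zip(enc["encounter_id"], enc["date"]):
        mem = [m for m in members.get(eid, []) if m in col]
        if not mem:
            continue
        p = (date - origin).days // period_length_days
        buckets.setdefault(p, []).append((eid, mem))

    starts, mats, eids = [], [], []
    for p in sorted(buckets):
        rows = buckets[p]
        m = np.zeros((len(rows), len(id_list)), dtype=np.uint8)
        for r, (_, mem) in enumerate(rows):
            for ind in mem:
                m[r, col[ind]] = 1
        starts.append(origin + dt.timedelta(days=p * period_length_days))
        mats.append(m)
        eids.append([eid for eid, _ in rows])
    return PeriodMatrices(ids=id_list, period_starts=starts,
                          period_length_days=period_length_days,
                          matrices=mats, encounter_ids=eids)
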