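"""Observation-level data model and tabular input/output.

A fish-community anomaly survey records, per inspected fish, the stream
reach it came from, its species, the collecting agency, the ecoregion and
year, and either a pre-aggregated binary DELT flag (deformity, erosion,
lesion, tumor, parasite) or per-category anomaly flags. Agencies differ in
which anomaly categories they assess and count, so per-category flags are
harmonized to the binary DELT outcome through an agency crosswalk table.

The working in-memory container is a :class:`pandas.DataFrame` with the
canonical columns in :data:`OBSERVATION_COLUMNS`; :class:`FishObservation`
is the record-level view of a single row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CrosswalkError,
    EmptyDataError,
    RowParseError,
    SchemaError,
)

OBSERVATION_COLUMNS = ("stream_id", "species", "agency", "ecoregion", "year", "delt")

#: Canonical anomaly categories that a crosswalk may count or exclude.
ANOMALY_CATEGORIES = ("deformity", "erosion", "lesion", "tumor", "parasite", "other")

#: Allowed per-record anomaly flag states.
FLAG_STATES = ("present", "absent", "not_assessed")

_FLAG_ALIASES = {
    "present": "present",
    "1": "present",
    "absent": "absent",
    "0": "absent",
    "not_assessed": "not_assessed",
    "na": "not_assessed",
    "": "not_assessed",
}


@dataclass(frozen=True)
class FishObservation:
    """One inspected fish: where, what, who collected it, and its DELT flag."""

    stream_id: str
    species: str
    agency: str
    ecoregion: str
    year: int
    delt: int

    def __post_init__(self):
        if self.delt not in (0, 1):
            raise ValueError(f"delt must be 0 or 1, got {self.delt!r}")
        for name in ("species", "agency", "ecoregion"):
            if not getattr(self, name):
                raise ValueError(f"{name} label must be non-empty")


@dataclass(frozen=True)
class AnomalyRecord:
    """Per-category anomaly flags for one fish.

    Each flag is one of ``present``, ``absent`` or ``not_assessed`` (an
    agency that never evaluates a category reports it as not assessed).
    """

    flags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for cat, state in self.flags.items():
            if cat not in ANOMALY_CATEGORIES:
                raise ValueError(f"unknown anomaly category {cat!r}")
            if state not in FLAG_STATES:
                raise ValueError(f"unknown flag state {state!r} for {cat!r}")


class CrosswalkTable:
    """Per-agency mapping of anomaly categories to counted/excluded.

    Agencies disagree on what enters the DELT aggregate (for example most
    count external parasites while the EPA protocol does not), so the
    crosswalk is user-supplied data rather than a hard-coded rule.
    """

    def __init__(self, mapping: Mapping[str, Mapping[str, str]]):
        self._map: dict[str, dict[str, str]] = {}
        for agency, row in mapping.items():
            agency = str(agency).strip()
            clean = {}
            for cat, status in row.items():
                if cat not in ANOMALY_CATEGORIES:
                    raise CrosswalkError(f"unknown anomaly category {cat!r} for agency {agency!r}")
                if status not in ("counted", "excluded"):
                    raise CrosswalkError(f"unknown crosswalk status {status!r} for {agency}/{cat}")
                clean[cat] = status
            self._map[agency] = clean

    @property
    def agencies(self) -> tuple[str, ...]:
        return tuple(self._map)

    def counted_categories(self, agency: str) -> frozenset[str]:
        if agency not in self._map:
            raise CrosswalkError(f"agency {agency!r} has no crosswalk row")
        row = self._map[agency]
        return frozenset(c for c, s in row.items() if s == "counted")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CrosswalkTable":
        """Build from a long table with columns agency, category, status."""
        for col in ("agency", "category", "status"):
            if col not in frame.columns:
                raise SchemaError(f"crosswalk table missing column {col!r}")
        mapping: dict[str, dict[str, str]] = {}
        for _, row in frame.iterrows():
            mapping.setdefault(str(row["agency"]).strip(), {})[str(row["category"]).strip()] = str(
                row["status"]
            ).strip()
        return cls(mapping)

    @classmethod
    def read_csv(cls, path) -> "CrosswalkTable":
        return cls.from_frame(pd.read_csv(path, dtype=str))


@dataclass(frozen=True)
class PrevalenceSummary:
    """Naive (non-model) DELT prevalence for one group of observations."""

    group: str
    n_inspected: int
    n_delt: int
    prevalence: float

    def __post_init__(self):
        if not 0 <= self.n_delt <= self.n_inspected:
            raise ValueError("need 0 <= n_delt <= n_inspected")


def read_fish_observations(
    path,
    schema: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read per-fish observation rows from a CSV file.

    Parameters
    ----------
    path
        Delimited text file with a header row (UTF-8).
    schema
        Optional map from canonical column names (``stream_id``, ``species``,
        ``agency``, ``ecoregion``, ``year``, ``delt``, and the anomaly
        categories) to the file's column names. Unmapped names are looked up
        verbatim.

    Returns
    -------
    observations, anomalies
        ``observations`` has the canonical columns (``delt`` may be absent
        when only anomaly flags were recorded and still need the crosswalk);
        ``anomalies`` has one column per recorded anomaly category with
        values in :data:`FLAG_STATES` (empty frame in passthrough mode).
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")

    def col(canonical: str) -> str:
        return schema.get(canonical, canonical)

    required = ("stream_id", "species", "agency", "ecoregion", "year")
    for canonical in required:
        if col(canonical) not in raw.columns:
            raise SchemaError(f"missing required column {col(canonical)!r} (for {canonical!r})")

    has_delt = col("delt") in raw.columns
    anomaly_cols = [c for c in ANOMALY_CATEGORIES if col(c) in raw.columns]
    if not has_delt and not anomaly_cols:
        raise SchemaError("file provides neither a 'delt' column nor anomaly flag columns")

    obs = pd.DataFrame(
        {
            "stream_id": raw[col("stream_id")].str.strip(),
            "species": raw[col("species")].str.strip(),
            "agency": raw[col("agency")].str.strip(),
            "ecoregion": raw[col("ecoregion")].str.strip(),
        }
    )
    years = pd.to_numeric(raw[col("year")], errors="coerce")
    bad = np.flatnonzero(years.isna().to_numpy())
    if bad.size:
        raise RowParseError(f"unparseable year {raw[col('year')].iloc[bad[0]]!r}", row=int(bad[0]))
    obs["year"] = years.astype(int)

    for name in ("species", "agency", "ecoregion"):
        if (obs[name] == "").any():
            row = int(np.flatnonzero((obs[name] == "").to_numpy())[0])
            raise RowParseError(f"empty {name} label", row=row)

    if has_delt:
        delt = pd.to_numeric(raw[col("delt")], errors="coerce")
        bad = np.flatnonzero((~delt.isin([0, 1])).to_numpy())
        if bad.size:
            raise RowParseError(
                f"delt flag must be 0 or 1, got {raw[col('delt')].iloc[bad[0]]!r}", row=int(bad[0])
            )
        obs["delt"] = delt.astype(int)

    anomalies = pd.DataFrame(index=raw.index)
    for cat in anomaly_cols:
        vals = raw[col(cat)].str.strip().str.lower()
        mapped = vals.map(_FLAG_ALIASES)
        bad = np.flatnonzero(mapped.isna().to_numpy())
        if bad.size:
            raise RowParseError(
                f"bad {cat} flag {raw[col(cat)].iloc[bad[0]]!r}", row=int(bad[0])
            )
        anomalies[cat] = mapped
    if not anomaly_cols:
        anomalies = pd.DataFrame()
    return obs, anomalies


def write_observations(observations: pd.DataFrame, path) -> None:
    """Write canonical observation columns to CSV (UTF-8, header row)."""
    observations.loc[:, [c for c in OBSERVATION_COLUMNS if c in observations.columns]].to_csv(
        path, index=False
    )


def filter_observation_window(
    observations: pd.DataFrame, start_year: int, end_year: int
) -> pd.DataFrame:
    """Keep observations with ``start_year <= year <= end_year`` (inclusive)."""
    if start_year > end_year:
        raise ValueError(f"inverted year window [{start_year}, {end_year}]")
    keep = (observations["year"] >= start_year) & (observations["year"] <= end_year)
    return observations.loc[keep].reset_index(drop=True)


def crosswalk_anomalies(record: AnomalyRecord, agency: str, crosswalk: CrosswalkTable) -> int:
    """Aggregate one fish's anomaly flags to a binary DELT outcome.

    Returns 1 iff at least one category the agency's crosswalk marks
    ``counted`` is flagged ``present``; not-assessed and excluded
    categories never contribute.
    """
    counted = crosswalk.counted_categories(agency)
    return int(any(record.flags.get(cat) == "present" for cat in counted))


def apply_crosswalk(
    observations: pd.DataFrame, anomalies: pd.DataFrame, crosswalk: CrosswalkTable
) -> pd.DataFrame:
    """Vectorized crosswalk: attach a ``delt`` column computed per agency.

    Rows that already carry a binary ``delt`` (the passthrough case where an
    agency reported only the aggregate) keep it verbatim.
    """
    out = observations.copy()
    if "delt" not in out.columns:
        out["delt"] = np.nan
    need = out["delt"].isna()
    if need.any():
        if anomalies.empty:
            raise SchemaError("observations lack a delt flag and no anomaly columns were given")
        delt = np.zeros(len(out), dtype=int)
        for agency in out.loc[need, "agency"].unique():
            counted = crosswalk.counted_categories(agency)
            rows = need & (out["agency"] == agency)
            hit = np.zeros(int(rows.sum()), dtype=bool)
            for cat in counted:
                if cat in anomalies.columns:
                    hit |= (anomalies.loc[rows.to_numpy(), cat] == "present").to_numpy()
            delt[rows.to_numpy()] = hit.astype(int)
        out.loc[need, "delt"] = delt[need.to_numpy()]
    out["delt"] = out["delt"].astype(int)
    return out


def compute_naive_prevalence(
    observations: pd.DataFrame, group_by: str = "overall"
) -> pd.DataFrame:
    """Observed (non-model) DELT prevalence, overall or per species/stream.

    Returns one row per group with ``n_inspected``, ``n_delt`` and
    ``prevalence = n_delt / n_inspected``; groups with zero inspected fish
    do not appear.
    """
    if len(observations) == 0:
        raise EmptyDataError("no observations")
    if group_by == "overall":
        keys = pd.Series("overall", index=observations.index, name="group")
    elif group_by == "species":
        keys = observations["species"].rename("group")
    elif group_by == "stream":
        keys = observations["stream_id"].rename("group")
    else:
        raise ValueError(f"group_by must be overall|species|stream, got {group_by!r}")
    grouped = observations.assign(group=keys).groupby("group", sort=True)["delt"]
    out = grouped.agg(n_inspected="size", n_delt="sum").reset_index()
    out["prevalence"] = out["n_delt"] / out["n_inspected"]
    return out


def select_focal_species(
    species_summaries: pd.DataFrame, min_prevalence: float = 0.05, min_n: int = 100
) -> list[str]:
    """Species eligible for a species-specific model.

    A species qualifies when its naive prevalence is at least
    ``min_prevalence`` *and* its sample size strictly exceeds ``min_n``
    (defaults 5% and 100). The returned list is sorted, so it does not
    depend on input row order.
    """
    if len(species_summaries) == 0:
        return []
    ok = (species_summaries["prevalence"] >= min_prevalence) & (
        species_summaries["n_inspected"] > min_n
    )
    return sorted(species_summaries.loc[ok, "group"].tolist())


def observations_from_records(records: Iterable[FishObservation]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(OBSERVATION_COLUMNS))


def records_from_observations(observations: pd.DataFrame) -> list[FishObservation]:
    return [
        FishObservation(
            stream_id=str(r.stream_id),
            species=str(r.species),
            agency=str(r.agency),
            ecoregion=str(r.ecoregion),
            year=int(r.year),
            delt=int(r.delt),
        )
        for r in observations.itertuples(index=False)
    ]
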