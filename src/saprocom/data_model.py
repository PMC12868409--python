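"""Core domain types for the deadwood emergence survey.

The survey follows individual deadwood logs of three tree species
(Norway spruce, silver fir, European beech) through decomposition,
recording every beetle species emerging from each log in each calendar
year.  Spruce logs were exposed one year later than beech and fir, so
calendar years are mapped to *years since exposure* per log via the
per-log ``exposure_start`` stored in :class:`SurveyDesign`; the spruce
"year 0" convention is thus data, not code.  A missing sampling year
(no collections at all) is represented simply by absent rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREE_SPECIES = ("spruce", "fir", "beech")

__all__ = [
    "TREE_SPECIES",
    "SurveyDesign",
    "CommunityTable",
    "OverlapSummary",
    "read_community",
    "summarize_overlap",
    "assemblage_matrix",
]


@dataclass(frozen=True)
class SurveyDesign:
    """Spatial and temporal layout of the log-exposure experiment.

    Parameters
    ----------
    logs : pandas.DataFrame
        One row per log with columns ``log_id``, ``tree_species``
        (one of :data:`TREE_SPECIES`), ``plot_id``, ``E``, ``N``
        (projected coordinates in metres) and ``exposure_start``
        (calendar year counting as exposure year zero).
    sampling_years : tuple of int
        Calendar years in which traps were emptied.
    missing_years : frozenset of int
        Calendar years inside the span of ``sampling_years`` with no
        sampling at all.
    """

    logs: pd.DataFrame
    sampling_years: tuple[int, ...]
    missing_years: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        required = {"log_id", "tree_species", "plot_id", "E", "N", "exposure_start"}
        missing = required - set(self.logs.columns)
        if missing:
            raise ValueError(f"design table lacks columns: {sorted(missing)}")
        if self.logs["log_id"].duplicated().any():
            raise ValueError("duplicate log_id in design")
        bad = set(self.logs["tree_species"]) - set(TREE_SPECIES)
        if bad:
            raise ValueError(f"unknown tree species: {sorted(bad)}")
        if not np.isfinite(self.logs[["E", "N"]].to_numpy(float)).all():
            raise ValueError("non-finite log coordinates")
        if self.sampling_years:
            lo, hi = min(self.sampling_years), max(self.sampling_years)
            out = {y for y in self.missing_years if not lo <= y <= hi}
            if out:
                raise ValueError(f"missing_years outside sampling span: {sorted(out)}")

    @property
    def log_ids(self) -> list[str]:
        return list(self.logs["log_id"])

    def tree_species_of(self, log_id: str) -> str:
        return self._log_attr("tree_species")[log_id]

    def exposure_start_of(self, log_id: str) -> int:
        return int(self._log_attr("exposure_start")[log_id])

    def _log_attr(self, col: str) -> dict:
        return dict(zip(self.logs["log_id"], self.logs[col]))

    def exposure_year(self, log_id: str, calendar_year: int) -> int:
        """Years since exposure for ``log_id`` in ``calendar_year``."""
        return int(calendar_year) - self.exposure_start_of(log_id)

    def to_csv(self, path) -> None:
        df = self.logs.copy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sampling_years, missing_years=()) -> "SurveyDesign":
        logs = pd.read_csv(path)
        return cls(logs=logs, sampling_years=tuple(int(y) for y in sampling_years),
                   missing_years=frozenset(int(y) for y in missing_years))


class CommunityTable:
    """Emergence counts indexed by (log, exposure year, species).

    Wraps a long-format :class:`pandas.DataFrame` with columns
    ``log_id``, ``exposure_year`` (integer years since exposure),
    ``species_id`` and ``count`` (strictly positive integers).
    Duplicate keys are summed on construction.
    """

    COLUMNS = ("log_id", "exposure_year", "species_id", "count")

    def __init__(self, records: pd.DataFrame):
        df = records.loc[:, list(self.COLUMNS)].copy()
        df["exposure_year"] = df["exposure_year"].astype(int)
        df["count"] = df["count"].astype(int)
        if (df["count"] < 0).any():
            raise ValueError("negative counts")
        df = df[df["count"] > 0]
        df = (df.groupby(["log_id", "exposure_year", "species_id"], as_index=False,
                         sort=True)["count"].sum())
        if (df["exposure_year"] < 0).any():
            raise ValueError("negative exposure_year")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.records.equals(other.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species_id"].unique())

    @property
    def total_individuals(self) -> int:
        return int(self.records["count"].sum())

    def assemblage(self, log_id: str, exposure_year: int) -> dict[str, int]:
        """Species -> count map for one log in one exposure year."""
        sel = self.records[(self.records["log_id"] == log_id)
                           & (self.records["exposure_year"] == int(exposure_year))]
        return dict(zip(sel["species_id"], sel["count"]))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CommunityTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class OverlapSummary:
    """Per-tree-species totals and shared-species (Venn) counts."""

    species_per_tree: dict[str, int]
    individuals_per_tree: dict[str, int]
    pairwise_shared: dict[tuple[str, str], int]
    shared_all: int
    total_species: int
    total_individuals: int

    def to_json(self, path) -> None:
        payload = {
            "species_per_tree": self.species_per_tree,
            "individuals_per_tree": self.individuals_per_tree,
            "pairwise_shared": {"|".join(k): v for k, v in self.pairwise_shared.items()},
            "shared_all": self.shared_all,
            "total_species": self.total_species,
            "total_individuals": self.total_individuals,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_community(records_path, design_path, sampling_years,
                   missing_years=()) -> tuple[SurveyDesign, CommunityTable]:
    """Read calendar-year emergence records and map them to exposure years.

    The records CSV has columns ``log_id``, ``tree_species``,
    ``calendar_year``, ``species_id``, ``count``.  Exposure year is
    ``calendar_year - exposure_start`` of the log (per the design CSV);
    zero counts are dropped and duplicate keys summed.  Rows falling in
    a declared missing sampling year are kept but flagged with a
    warning, since they contradict the design.
    """
    design = SurveyDesign.from_csv(design_path, sampling_years, missing_years)
    raw = pd.read_csv(records_path)
    unknown = set(raw["log_id"]) - set(design.log_ids)
    if unknown:
        raise ValueError(f"records reference unknown log_id(s): {sorted(unknown)[:5]}")
    if (raw["count"] < 0).any():
        raise ValueError("negative counts in records")
    if "tree_species" in raw.columns:
        declared = dict(zip(design.logs["log_id"], design.logs["tree_species"]))
        mism = raw[raw["tree_species"] != raw["log_id"].map(declared)]
        if len(mism):
            raise ValueError("tree_species in records disagrees with design")
    in_missing = raw[(raw["calendar_year"].isin(design.missing_years)) & (raw["count"] > 0)]
    if len(in_missing):
        warnings.warn(
            f"{len(in_missing)} record(s) fall in declared missing sampling years; kept",
            UserWarning, stacklevel=2)
    starts = raw["log_id"].map(dict(zip(design.logs["log_id"],
                                        design.logs["exposure_start"])))
    out = pd.DataFrame({
        "log_id": raw["log_id"],
        "exposure_year": raw["calendar_year"].astype(int) - starts.astype(int),
        "species_id": raw["species_id"],
        "count": raw["count"].astype(int),
    })
    return design, CommunityTable(out)


def summarize_overlap(table: CommunityTable, design: SurveyDesign) -> OverlapSummary:
    """Species pools per tree species and their pairwise/three-way overlaps."""
    if len(table) == 0:
        raise ValueError("empty community table")
    tree_of = dict(zip(design.logs["log_id"], design.logs["tree_species"]))
    rec = table.records.assign(tree=table.records["log_id"].map(tree_of))
    pools = {t: set(rec.loc[rec["tree"] == t, "species_id"]) for t in TREE_SPECIES}
    indiv = {t: int(rec.loc[rec["tree"] == t, "count"].sum()) for t in TREE_SPECIES}
    pairs = {}
    for i, a in enumerate(TREE_SPECIES):
        for b in TREE_SPECIES[i + 1:]:
            pairs[(a, b)] = len(pools[a] & pools[b])
    return OverlapSummary(
        species_per_tree={t: len(pools[t]) for t in TREE_SPECIES},
        individuals_per_tree=indiv,
        pairwise_shared=pairs,
        shared_all=len(pools["spruce"] & pools["fir"] & pools["beech"]),
        total_species=len(set(rec["species_id"])),
        total_individuals=int(rec["count"].sum()),
    )


def assemblage_matrix(table: CommunityTable, design: SurveyDesign,
                      min_species: int = 0,
                      exclusions: set[tuple[str, int]] | None = None) -> pd.DataFrame:
    """Site x species count matrix over (log, exposure-year) assemblages.

    Rows are indexed by a MultiIndex ``(log_id, exposure_year)``; rows
    with fewer than ``min_species`` species are dropped, as are rows
    whose ``(tree_species, exposure_year)`` pair is listed in
    ``exclusions`` (the survey excludes spruce year-0 assemblages from
    compositional analyses because the other tree species were first
    sampled in exposure year 1).
    """
    if min_species < 0:
        raise ValueError("min_species must be >= 0")
    exclusions = set(exclusions or ())
    wide = table.records.pivot_table(index=["log_id", "exposure_year"],
                                     columns="species_id", values="count",
                                     aggfunc="sum", fill_value=0)
    tree_of = dict(zip(design.logs["log_id"], design.logs["tree_species"]))
    keep = []
    for log_id, year in wide.index:
        if (tree_of[log_id], year) in exclusions:
            keep.append(False)
        else:
            keep.append(int((wide.loc[(log_id, year)] > 0).sum()) >= min_species)
    wide = wide.loc[keep]
    wide = wide.loc[:, (wide > 0).any(axis=0)]
    if wide.empty:
        raise EmptyAssemblageError(
            f"no (log, year) assemblage passes min_species={min_species} "
            f"with {len(exclusions)} exclusion(s)")
    return wide


class EmptyAssemblageError(ValueError):
    """All assemblages were filtered out."""
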