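"""Score-table and metadata I/O.

Regional TDP-43 burden arrives as semi-quantitative ratings on the scale
0 = non-detectable, 0.5 = sparse, 1 = mild, 2 = moderate, 3 = severe, one
value per subject and sampled brain region, with missing cells where a
region was not sampled.  This module owns the on-disk CSV contract, scale
validation, the missing-data region filter, and the total-pathology summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: the legal semi-quantitative rating scale
RATING_SCALE = (0.0, 0.5, 1.0, 2.0, 3.0)

#: tokens interpreted as a missing cell by default (plus the empty cell)
DEFAULT_MISSING_TOKENS = ("", "NA")


class ScoreTableError(ValueError):
    """Malformed or out-of-scale score table."""


@dataclass
class RegionalScoreTable:
    """Subjects x regions ordinal rating matrix with per-subject group labels.

    ``scores`` is a DataFrame indexed by subject id with one column per
    region; missing cells are NaN.  Region column order is canonical: it
    defines region indexing for every downstream matrix.
    """

    scores: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ScoreTableError("duplicate subject ids")
        if self.scores.columns.has_duplicates:
            raise ScoreTableError("duplicate region names")
        values = self.scores.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        bad = ~np.isin(observed, RATING_SCALE)
        if bad.any():
            raise ScoreTableError(
                f"ratings outside the scale {RATING_SCALE}: "
                f"{sorted(set(observed[bad]))}"
            )
        if self.groups is not None:
            self.groups = self.groups.reindex(self.scores.index)

    @property
    def subject_ids(self) -> list:
        return list(self.scores.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.scores.index)

    @property
    def n_regions(self) -> int:
        return len(self.scores.columns)

    def missing_fraction(self) -> pd.Series:
        """Per-region fraction of subjects with a missing rating."""
        return self.scores.isna().mean(axis=0)

    def subset(self, subject_ids: Sequence) -> "RegionalScoreTable":
        missing = [s for s in subject_ids if s not in self.scores.index]
        if missing:
            raise KeyError(f"unknown subjects: {missing}")
        groups = self.groups.loc[subject_ids] if self.groups is not None else None
        return RegionalScoreTable(self.scores.loc[list(subject_ids)], groups)


@dataclass
class CohortMetadata:
    """Per-subject covariates: ages, duration, sex, PMI, Braak, APOE, TDP type."""

    table: pd.DataFrame

    NUMERIC = ("age_at_onset", "age_at_death", "disease_duration",
               "post_mortem_interval", "braak_stage")

    def __post_init__(self) -> None:
        t = self.table
        if {"age_at_onset", "age_at_death", "disease_duration"} <= set(t.columns):
            both = t["age_at_onset"].notna() & t["age_at_death"].notna()
            dur = t.loc[both, "age_at_death"] - t.loc[both, "age_at_onset"]
            stated = t.loc[both, "disease_duration"]
            ok = stated.isna() | np.isclose(stated, dur, atol=1e-6)
            if not ok.all():
                bad = list(t.index[both][~ok])
                raise ScoreTableError(
                    f"disease_duration != age_at_death - age_at_onset for {bad}"
                )

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]


def load_schema_config(path: str | Path) -> dict:
    """Read a YAML schema config (missing-value tokens, id column name)."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def read_score_table(
    path: str | Path,
    schema_config: dict | None = None,
) -> RegionalScoreTable:
    """Read a subject x region rating CSV.

    First column holds subject ids, remaining columns one region each.
    ``schema_config`` keys: ``missing_tokens`` (list of strings read as
    missing; the empty cell always counts), ``group_column`` (optional
    column holding the diagnostic group label).
    """
    cfg = schema_config or {}
    tokens = list(cfg.get("missing_tokens", DEFAULT_MISSING_TOKENS))
    try:
        df = pd.read_csv(path, index_col=0, na_values=tokens,
                         keep_default_na=False, skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ScoreTableError(f"malformed CSV {path}: {exc}") from exc

    groups = None
    group_col = cfg.get("group_column", "group")
    if group_col in df.columns:
        groups = df.pop(group_col).astype(str)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    unparsable = numeric.isna() & df.notna()
    if unparsable.any().any():
        row, col = next(zip(*np.nonzero(unparsable.to_numpy())))
        raise ScoreTableError(
            f"non-numeric rating at subject {df.index[row]!r}, "
            f"region {df.columns[col]!r}: {df.iloc[row, col]!r}"
        )
    return RegionalScoreTable(numeric, groups)


def write_score_table(table: RegionalScoreTable, path: str | Path) -> None:
    """Write a table back to CSV (NaN as empty cell); inverse of read."""
    df = table.scores.copy()
    if table.groups is not None:
        df.insert(0, "group", table.groups)
    df.to_csv(path, index_label="subject_id")


def read_metadata(path: str | Path) -> CohortMetadata:
    df = pd.read_csv(path, index_col=0)
    return CohortMetadata(df)


def filter_regions_by_missingness(
    table: RegionalScoreTable, threshold: float = 0.25
) -> tuple[RegionalScoreTable, list[str]]:
    """Drop regions whose missing fraction strictly exceeds ``threshold``.

    Returns the filtered table (original region order preserved) and the
    list of excluded region names.  A region missing in exactly the
    threshold fraction of subjects is retained.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    frac = table.missing_fraction()
    excluded = [r for r in table.region_names if frac[r] > threshold]
    kept = [r for r in table.region_names if r not in excluded]
    if not kept:
        raise ScoreTableError("all regions exceed the missingness threshold")
    return RegionalScoreTable(table.scores[kept], table.groups), excluded


def total_pathology(table: RegionalScoreTable, subject) -> float:
    """Sum of a subject's non-missing regional ratings (missing counts 0)."""
    if subject not in table.scores.index:
        raise KeyError(f"unknown subject {subject!r}")
    return float(table.scores.loc[subject].sum(skipna=True))


def total_pathology_all(table: RegionalScoreTable) -> pd.Series:
    """Total pathology for every subject, in table order."""
    return table.scores.sum(axis=1, skipna=True)
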