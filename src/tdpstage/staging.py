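"""Heuristic literature staging schemes and their comparison to model stages.

A staging scheme is an ordered list of stages, each owning a set of brain
regions.  A subject's composite score for a stage is the mean of their
non-missing ratings over that stage's regions.  The subject is assigned
the highest stage m such that every stage up to m has composite >= 1
("mild" pathology); if a later stage reaches threshold while an earlier
one does not, the pattern is out of order and the subject is
Unclassifiable; if no stage reaches threshold the subject is stage 0.

The shipped scheme files are PROVISIONAL region memberships reconstructed
from the staging literature (the exact per-stage region lists are not
bundled); they are plain YAML and meant to be edited.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from .assignment import SubjectAssignment
from .io import RegionalScoreTable

UNCLASSIFIABLE = "Unclassifiable"
STAGE_ZERO = "0"


@dataclass(frozen=True)
class StagingScheme:
    name: str
    stage_labels: tuple[str, ...]
    stage_regions: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.stage_labels:
            raise ValueError("scheme has no stages")
        if len(self.stage_labels) != len(self.stage_regions):
            raise ValueError("one region list per stage required")
        if any(len(r) == 0 for r in self.stage_regions):
            raise ValueError("empty stage region list")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    def validate_regions(self, table: RegionalScoreTable) -> None:
        known = set(table.region_names)
        missing = sorted(
            {r for regions in self.stage_regions for r in regions} - known
        )
        if missing:
            raise KeyError(
                f"scheme {self.name!r} references regions absent from the "
                f"table: {missing}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StagingScheme":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            payload["name"],
            tuple(str(s["label"]) for s in payload["stages"]),
            tuple(tuple(s["regions"]) for s in payload["stages"]),
        )


def builtin_scheme(name: str) -> StagingScheme:
    """Load a bundled provisional scheme by file stem.

    Available: brettschneider_als, brettschneider_bvftd, nelson_late,
    josephs_late, rush_late.
    """
    ref = resources.files("tdpstage") / "schemes" / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"no bundled scheme named {name!r}")
    payload = yaml.safe_load(ref.read_text())
    return StagingScheme(
        payload["name"],
        tuple(str(s["label"]) for s in payload["stages"]),
        tuple(tuple(s["regions"]) for s in payload["stages"]),
    )


def composite_stage_scores(
    table: RegionalScoreTable, scheme: StagingScheme, subject
) -> np.ndarray:
    """Per-stage mean of the subject's non-missing member-region ratings.

    A stage whose member regions are all missing yields NaN (undefined);
    callers should flag such subjects.
    """
    scheme.validate_regions(table)
    if subject not in table.scores.index:
        raise KeyError(f"unknown subject {subject!r}")
    row = table.scores.loc[subject]
    out = np.empty(scheme.n_stages)
    for i, regions in enumerate(scheme.stage_regions):
        vals = row[list(regions)].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        out[i] = vals.mean() if vals.size else np.nan
    return out


def assign_heuristic_stage(
    composites: np.ndarray,
    scheme: StagingScheme | None = None,
    threshold: float = 1.0,
    strict: bool = False,
) -> str:
    """Stage label from composite scores by the cumulative >= 1 rule.

    ``strict=True`` switches the criterion to strictly greater-than.
    NaN composites (stage undefined) never reach threshold.
    """
    comp = np.asarray(composites, dtype=float)
    with np.errstate(invalid="ignore"):
        meets = comp > threshold if strict else comp >= threshold
    meets = np.where(np.isnan(comp), False, meets)
    if not meets.any():
        return STAGE_ZERO
    # highest m with all stages 1..m at threshold
    run = 0
    while run < meets.size and meets[run]:
        run += 1
    if meets[run:].any():
        return UNCLASSIFIABLE
    if scheme is not None:
        return scheme.stage_labels[run - 1]
    return _roman(run)


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1] if 1 <= n <= len(numerals) else str(n)


def stage_subjects(
    table: RegionalScoreTable,
    scheme: StagingScheme,
    threshold: float = 1.0,
    strict: bool = False,
) -> pd.DataFrame:
    """Heuristic stage for every subject: columns stage, undefined_stages."""
    scheme.validate_regions(table)
    rows = []
    for subject in table.subject_ids:
        comp = composite_stage_scores(table, scheme, subject)
        label = assign_heuristic_stage(comp, scheme, threshold, strict)
        rows.append(
            {
                "subject_id": subject,
                "stage": label,
                "undefined_stages": int(np.isnan(comp).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


@dataclass
class StageAgreement:
    crosstab: pd.DataFrame
    rank_correlation: float
    p_value: float
    n_classifiable: int


def _heuristic_rank(label: str, scheme: StagingScheme) -> float:
    if label == STAGE_ZERO:
        return 0.0
    return float(scheme.stage_labels.index(label) + 1)


def compare_to_sustain(
    heuristic_stages: pd.Series,
    assignments: list[SubjectAssignment],
    scheme: StagingScheme,
) -> StageAgreement:
    """Cross-tabulate heuristic vs data-driven stage; Spearman correlation
    over classifiable subjects (Unclassifiable kept as its own row)."""
    model_stage = pd.Series(
        {a.subject_id: a.ml_stage for a in assignments}, name="model_stage"
    )
    if set(model_stage.index) != set(heuristic_stages.index):
        raise ValueError("subject sets differ between inputs")
    heuristic_stages = heuristic_stages.reindex(model_stage.index)
    order = [STAGE_ZERO, *scheme.stage_labels, UNCLASSIFIABLE]
    crosstab = pd.crosstab(heuristic_stages, model_stage).reindex(
        [s for s in order if s in set(heuristic_stages)]
    )
    classifiable = heuristic_stages != UNCLASSIFIABLE
    n = int(classifiable.sum())
    if n >= 3:
        ranks = heuristic_stages[classifiable].map(
            lambda s: _heuristic_rank(s, scheme)
        )
        rho, p = spearmanr(ranks, model_stage[classifiable])
        rho, p = float(rho), float(p)
    else:
        rho, p = float("nan"), float("nan")
    return StageAgreement(crosstab, rho, p, n)
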