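"""Cohort-level statistics over pipeline outputs.

Covers the downstream comparisons: correlations between model stage and
age/duration/total pathology, the classifiable-vs-unclassifiable t-test on
model-fit probability, and the region-wise GLM contrasting subtypes with
stage as a nuisance covariate, corrected across regions by the
Benjamini-Hochberg false discovery rate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .assignment import SubjectAssignment
from .io import RegionalScoreTable
from .staging import UNCLASSIFIABLE


def _stage_series(assignments: list[SubjectAssignment]) -> pd.Series:
    return pd.Series({a.subject_id: a.ml_stage for a in assignments})


def stage_association(
    assignments: list[SubjectAssignment],
    values: pd.Series,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between assigned stage and a per-subject variable.

    ``values`` is indexed by subject id (age at onset/death, duration, or
    total pathology).  Returns (r, two-sided p).  Pearson by default,
    ``method='spearman'`` for the rank version.
    """
    stages = _stage_series(assignments)
    df = pd.concat([stages.rename("stage"), values.rename("value")], axis=1)
    df = df.dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete (stage, value) pairs")
    if df["stage"].nunique() < 2 or df["value"].nunique() < 2:
        raise ValueError("zero variance in stage or value")
    if method == "pearson":
        r, p = sps.pearsonr(df["stage"], df["value"])
    elif method == "spearman":
        r, p = sps.spearmanr(df["stage"], df["value"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def classifiable_vs_unclassifiable_test(
    heuristic_stages: pd.Series,
    fit_probabilities: pd.Series,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided independent-samples t-test (Welch by default) on the
    model-fit probability of heuristically classifiable vs unclassifiable
    subjects.  Positive t means classifiable subjects fit better."""
    stages = heuristic_stages.reindex(fit_probabilities.index)
    unclassifiable = stages == UNCLASSIFIABLE
    a = fit_probabilities[~unclassifiable].dropna()
    b = fit_probabilities[unclassifiable].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 subjects")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, never below p)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def regionwise_subtype_glm(
    table: RegionalScoreTable,
    assignments: list[SubjectAssignment],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region OLS of score ~ subtype + stage, BH-corrected across regions.

    The subtype regressor is an indicator for subtype 1 (the
    largest-fraction subtype, index 0), so a positive t means more severe
    pathology in subtype 1.  Regions with a rank-deficient or empty design
    are skipped with a warning.  Returns a tidy frame indexed by region
    with columns t, p, q, significant.
    """
    subtypes = pd.Series({a.subject_id: a.subtype for a in assignments})
    if subtypes.nunique() < 2:
        raise ValueError("need two subtypes present for the contrast")
    stages = _stage_series(assignments)
    rows = {}
    for region in table.region_names:
        y = table.scores[region].reindex(subtypes.index)
        df = pd.DataFrame(
            {
                "score": y,
                "subtype1": (subtypes == 0).astype(float),
                "stage": stages.astype(float),
            }
        ).dropna()
        if len(df) < 4 or df["subtype1"].nunique() < 2:
            warnings.warn(f"region {region!r} skipped: degenerate design")
            continue
        X = sm.add_constant(df[["subtype1", "stage"]])
        fit = sm.OLS(df["score"], X).fit()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"region {region!r} skipped: rank-deficient design")
            continue
        rows[region] = {
            "t": float(fit.tvalues["subtype1"]),
            "p": float(fit.pvalues["subtype1"]),
        }
    if not rows:
        raise ValueError("no region yielded a valid model")
    out = pd.DataFrame(rows).T
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out.index.name = "region"
    return out
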