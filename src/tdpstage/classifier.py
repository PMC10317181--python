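"""Three-way diagnosis prediction from progression-model outputs.

Two classifiers are provided.  The winner-takes-all rule predicts the
group whose progression model gives the subject the highest fit
probability, labelling subjects whose winning model stages them at 0 as
"Unclassified" (not enough pathology to classify; excluded from metrics).
The second classifier feeds the per-group fit probabilities plus the
maximum-likelihood stage and age at death into an L2-penalised multinomial
logistic regression, tuned by inner cross-validation over a grid of 10
linearly spaced C values between 1e-4 and 1e4 and evaluated over repeated
80/20 train/test splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import GridSearchCV, train_test_split

UNCLASSIFIED = "Unclassified"


def classify_max_likelihood(
    fit_probs: pd.DataFrame, ml_stages: pd.DataFrame
) -> pd.Series:
    """Winner-takes-all over group models.

    ``fit_probs``: subjects x group-model fit probabilities; ``ml_stages``:
    the maximum-likelihood stage of each subject under each group model
    (same shape).  Column order defines the deterministic tie-break.  A
    subject whose most probable model assigns stage 0 is "Unclassified".
    """
    if list(fit_probs.columns) != list(ml_stages.columns) or not fit_probs.index.equals(
        ml_stages.index
    ):
        raise ValueError("fit_probs and ml_stages must be aligned")
    values = fit_probs.to_numpy(dtype=float)
    winner = np.argmax(values, axis=1)  # first maximiser: column-order ties
    ties = (values == values.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} exact tie(s) resolved by column order "
            f"{list(fit_probs.columns)}"
        )
    labels = fit_probs.columns.to_numpy()[winner]
    winning_stage = ml_stages.to_numpy()[np.arange(len(winner)), winner]
    labels = np.where(winning_stage == 0, UNCLASSIFIED, labels)
    return pd.Series(labels, index=fit_probs.index, name="predicted")


def classification_metrics(
    true_labels, predicted_labels
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix and metric table (accuracy, balanced accuracy,
    per-class and weighted precision/recall/F1)."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    classes = sorted(set(y_true) | set(y_pred))
    cm = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=classes),
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent predicted classes
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0
        )
        w_prec, w_rec, w_f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="weighted", zero_division=0
        )
    rows = {
        c: {"precision": prec[i], "recall": rec[i], "f1": f1[i],
            "support": support[i]}
        for i, c in enumerate(classes)
    }
    rows["weighted"] = {
        "precision": w_prec, "recall": w_rec, "f1": w_f1,
        "support": support.sum(),
    }
    metrics = pd.DataFrame(rows).T
    metrics.attrs["accuracy"] = float((y_true == y_pred).mean())
    metrics.attrs["balanced_accuracy"] = float(
        balanced_accuracy_score(y_true, y_pred)
    )
    return cm, metrics


def accuracy_excluding_unclassified(
    true_labels: pd.Series, predicted: pd.Series
) -> float:
    """Accuracy over subjects with a definite prediction."""
    mask = predicted != UNCLASSIFIED
    if not mask.any():
        raise ValueError("all subjects are Unclassified")
    return float((true_labels[mask] == predicted[mask]).mean())


@dataclass
class LogisticConfig:
    """Settings for the repeated-split logistic-regression classifier."""

    n_repeats: int = 100
    test_fraction: float = 0.2
    inner_folds: int = 10
    n_c_values: int = 10
    c_min: float = 1e-4
    c_max: float = 1e4
    log_spaced: bool = False
    max_iter: int = 2000
    max_split_retries: int = 20
    seed: int = 0

    def c_grid(self) -> np.ndarray:
        if self.log_spaced:
            return np.logspace(
                np.log10(self.c_min), np.log10(self.c_max), self.n_c_values
            )
        return np.linspace(self.c_min, self.c_max, self.n_c_values)


@dataclass
class LogisticResult:
    classifier: GridSearchCV
    split_metrics: pd.DataFrame      # one row per repeat
    summary: pd.DataFrame            # mean and 2.5/97.5 percentiles
    mean_confusion: pd.DataFrame


def _resampled_split(X, y, cfg: LogisticConfig, rng: np.random.Generator):
    classes = np.unique(y)
    for _ in range(cfg.max_split_retries):
        seed = int(rng.integers(2**31))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=cfg.test_fraction, random_state=seed
        )
        if set(classes) <= set(y_tr) and len(set(y_te)) >= 1:
            return X_tr, X_te, y_tr, y_te
    raise RuntimeError("could not draw a split containing every class")


def classify_logistic(
    features: pd.DataFrame,
    labels: pd.Series,
    config: LogisticConfig | None = None,
) -> LogisticResult:
    """L2 multinomial logistic regression on model-fit features.

    ``features`` columns are typically the per-group fit probabilities,
    the maximum-likelihood stage, and age at death.  Each repeat draws an
    80/20 split, tunes C by inner 10-fold CV on the training part with an
    lbfgs solver, and records test-set metrics; the returned classifier is
    refit on the full sample with the same tuning procedure.
    """
    cfg = config or LogisticConfig()
    if features.isna().any().any():
        raise ValueError("features contain missing values")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    X = features.to_numpy(dtype=float)
    rng = np.random.default_rng(cfg.seed)
    grid = {"C": cfg.c_grid()}
    classes = sorted(np.unique(y))

    records = []
    cms = []
    for _ in range(cfg.n_repeats):
        X_tr, X_te, y_tr, y_te = _resampled_split(X, y, cfg, rng)
        search = GridSearchCV(
            LogisticRegression(
                penalty="l2", solver="lbfgs", max_iter=cfg.max_iter
            ),
            grid,
            cv=cfg.inner_folds,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X_tr, y_tr)
        y_hat = search.predict(X_te)
        cm, metrics = classification_metrics(y_te, y_hat)
        cms.append(cm.reindex(index=classes, columns=classes, fill_value=0))
        row = {
            "accuracy": metrics.attrs["accuracy"],
            "balanced_accuracy": metrics.attrs["balanced_accuracy"],
            "best_C": search.best_params_["C"],
        }
        for avg in ("weighted",):
            row[f"{avg}_precision"] = metrics.loc[avg, "precision"]
            row[f"{avg}_recall"] = metrics.loc[avg, "recall"]
            row[f"{avg}_f1"] = metrics.loc[avg, "f1"]
        records.append(row)
    split_metrics = pd.DataFrame(records)
    summary = split_metrics.describe(percentiles=[0.025, 0.975]).loc[
        ["mean", "2.5%", "97.5%"]
    ]
    mean_cm = sum(cms) / len(cms)

    final = GridSearchCV(
        LogisticRegression(penalty="l2", solver="lbfgs", max_iter=cfg.max_iter),
        grid,
        cv=cfg.inner_folds,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return LogisticResult(final, split_metrics, summary, mean_cm)
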