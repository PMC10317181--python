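"""Subject-level subtype and stage assignment.

A fitted model assigns each subject a subtype (the mixture component with
the highest fraction-weighted marginal likelihood) and a maximum-likelihood
stage along that subtype's sequence.  The stage posterior is averaged over
the MCMC sequence samples, so sequence uncertainty propagates into staging.
The maximum of that averaged posterior — the probability of the
maximum-likelihood stage — doubles as a bounded model-fit score that is
comparable across group models built on different region sets; it drives
the cross-diagnosis classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .inference import FitConfig, _marginal_ll, _stage_ll, fit_subtypes, stage_stratified_folds
from .progression import EventSequence, SubtypeModel, log_probability_tensor
from .score_model import ScoreProbabilityTensor


@dataclass
class SubjectAssignment:
    subject_id: object
    subtype: int
    ml_stage: int
    stage_posterior: np.ndarray    # over stages 0..M
    subtype_posterior: np.ndarray  # over subtypes
    fit_probability: float

    def __post_init__(self) -> None:
        if not np.isclose(self.stage_posterior.sum(), 1.0):
            raise ValueError("stage posterior must sum to 1")
        if not np.isclose(self.subtype_posterior.sum(), 1.0):
            raise ValueError("subtype posterior must sum to 1")


def _avg_stage_loglik(
    logp: np.ndarray, sequences: list[EventSequence]
) -> np.ndarray:
    """(S, M+1) log of the sample-averaged stage-conditional likelihood.

    Integrating over posterior sequence samples before normalising is the
    Bayesian treatment of sequence uncertainty: P(x | k) = mean_n
    P(x | k, sequence_n).
    """
    stack = np.stack(
        [_stage_ll(logp, seq.order) for seq in sequences], axis=0
    )
    return logsumexp(stack, axis=0) - np.log(len(sequences))


def _subtype_avg_loglik(
    logp: np.ndarray, model: SubtypeModel, c: int
) -> np.ndarray:
    chain = model.mcmc_samples[c] if model.mcmc_samples else []
    sequences = chain if chain else [model.sequences[c]]
    return _avg_stage_loglik(logp, sequences)


def _subtype_stage_posterior(
    logp: np.ndarray, model: SubtypeModel, c: int
) -> np.ndarray:
    """Stage posterior under subtype c, integrated over its MCMC samples."""
    return softmax(_subtype_avg_loglik(logp, model, c), axis=1)


def assign_subtype_and_stage(
    probs: ScoreProbabilityTensor, model: SubtypeModel
) -> list[SubjectAssignment]:
    """Assign every subject a subtype and a maximum-likelihood stage.

    Subtype: argmax_c f_c x stage-marginal likelihood under sequence c.
    Stage: argmax of the assigned subtype's MCMC-averaged stage posterior;
    ties break toward the lower stage / lower subtype index.
    """
    logp = log_probability_tensor(probs)
    per_c = np.stack(
        [_marginal_ll(logp, s.order) for s in model.sequences], axis=1
    )
    with np.errstate(divide="ignore"):
        weighted = per_c + np.log(model.fractions)[None, :]
    subtype_post = softmax(weighted, axis=1)
    subtype = np.argmax(weighted, axis=1)  # first maximiser on ties

    stage_post_per_c = [
        _subtype_stage_posterior(logp, model, c)
        for c in range(model.n_subtypes)
    ]
    out = []
    for i, sid in enumerate(probs.subject_ids):
        c = int(subtype[i])
        sp = stage_post_per_c[c][i]
        out.append(
            SubjectAssignment(
                subject_id=sid,
                subtype=c,
                ml_stage=int(np.argmax(sp)),
                stage_posterior=sp,
                subtype_posterior=subtype_post[i],
                fit_probability=float(sp.max()),
            )
        )
    return out


def assignments_frame(assignments: list[SubjectAssignment]) -> pd.DataFrame:
    """Tidy per-subject table of subtype, stage, and fit probability."""
    return pd.DataFrame(
        {
            "subject_id": [a.subject_id for a in assignments],
            "subtype": [a.subtype for a in assignments],
            "ml_stage": [a.ml_stage for a in assignments],
            "fit_probability": [a.fit_probability for a in assignments],
        }
    ).set_index("subject_id")


def fit_probabilities(
    probs: ScoreProbabilityTensor, model: SubtypeModel
) -> np.ndarray:
    """(S,) probability of the maximum-likelihood stage under ``model``.

    The stage posterior is computed per subtype (averaged over MCMC
    samples), mixed by the subtype posterior, and maximised over stages.
    For a single-subtype model this is the max of the averaged posterior.
    """
    logp = log_probability_tensor(probs)
    if model.n_subtypes == 1:
        post = _subtype_stage_posterior(logp, model, 0)
        return post.max(axis=1)
    per_c = np.stack(
        [_marginal_ll(logp, s.order) for s in model.sequences], axis=1
    )
    with np.errstate(divide="ignore"):
        w = softmax(per_c + np.log(model.fractions)[None, :], axis=1)
    post = sum(
        w[:, c : c + 1] * _subtype_stage_posterior(logp, model, c)
        for c in range(model.n_subtypes)
    )
    return post.max(axis=1)


def model_fit_probability(
    probs: ScoreProbabilityTensor,
    model: SubtypeModel,
    subject,
    subject_group: str | None = None,
    cv_fold_models: dict | None = None,
) -> float:
    """Fit probability of one subject under a group model.

    When the subject belongs to the model's own group, a ``cv_fold_models``
    map (subject id -> model fitted without that subject's fold) must be
    supplied so the evaluation is out-of-sample.
    """
    if subject_group is not None and subject_group == model.group_label:
        if cv_fold_models is None:
            raise ValueError(
                "within-group evaluation requires a CV fold-model map"
            )
        model = cv_fold_models[subject]
    i = probs.subject_ids.index(subject)
    sub = probs.subset([i])
    return float(fit_probabilities(sub, model)[0])


def model_avg_stage_loglik(
    probs: ScoreProbabilityTensor, model: SubtypeModel
) -> np.ndarray:
    """(S, M+1) log P(x | stage k, model): subtype mixture, MCMC-integrated."""
    logp = log_probability_tensor(probs)
    per_c = np.stack(
        [_subtype_avg_loglik(logp, model, c) for c in range(model.n_subtypes)],
        axis=0,
    )  # (C, S, M+1)
    with np.errstate(divide="ignore"):
        logf = np.log(model.fractions)
    return logsumexp(per_c + logf[:, None, None], axis=0)


def cross_validated_stage_logliks(
    probs: ScoreProbabilityTensor,
    model: SubtypeModel,
    config: FitConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Out-of-sample (S, M+1) stage log likelihoods for the model's own group.

    Refits the model on each training fold (folds stratified by stage
    tertile of the full-sample assignment) and evaluates each subject under
    the model that excluded their fold.  Returns the matrix and a
    subject -> fold-model map.
    """
    rng = rng if rng is not None else config.rng()
    assignments = assign_subtype_and_stage(probs, model)
    stages = np.array([a.ml_stage for a in assignments])
    folds = stage_stratified_folds(stages, config.n_folds, rng)
    S = probs.n_subjects
    avg_ll = np.zeros((S, model.event_set.n_events + 1))
    fold_models: dict = {}
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(S), test_idx)
        fold_model = fit_subtypes(
            probs.subset(train_idx), model.event_set, model.n_subtypes,
            config, rng, run_mcmc=True, group_label=model.group_label,
        )
        avg_ll[test_idx] = model_avg_stage_loglik(
            probs.subset(test_idx), fold_model
        )
        for i in test_idx:
            fold_models[probs.subject_ids[i]] = fold_model
    return avg_ll, fold_models


def cross_validated_fit_probabilities(
    probs: ScoreProbabilityTensor,
    model: SubtypeModel,
    config: FitConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Out-of-sample fit probabilities and maximum-likelihood stages for
    the model's own group; see cross_validated_stage_logliks."""
    avg_ll, fold_models = cross_validated_stage_logliks(
        probs, model, config, rng
    )
    post = softmax(avg_ll, axis=1)
    return post.max(axis=1), post.argmax(axis=1), fold_models


def joint_classification_probabilities(
    avg_logliks: dict[str, np.ndarray],
    region_counts: dict[str, int],
    subject_ids,
    universe: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probability of each (group model, stage) combination per subject.

    ``avg_logliks[g]`` is the (S, M_g+1) stage log likelihood under group
    model g (MCMC-integrated, out-of-sample for the subject's own group).
    Group models built on fewer regions would enjoy systematically larger
    likelihoods (fewer <= 1 factors), so each model is completed to the
    region universe by a uniform 1/4 factor per region it excludes — the
    same convention used for missing ratings.  Probabilities are normalised
    jointly across every (group, stage) pair with a uniform stage prior.

    Returns (per-group max-stage probability, per-group argmax stage);
    winner-takes-all classification feeds directly on these.
    """
    if universe is None:
        universe = max(region_counts.values())
    logits = {}
    for g, ll in avg_logliks.items():
        n_stages = ll.shape[1]
        penalty = (universe - region_counts[g]) * np.log(4.0)
        logits[g] = ll - np.log(n_stages) - penalty
    denom = logsumexp(
        np.concatenate(list(logits.values()), axis=1), axis=1, keepdims=True
    )
    fit_probs = {}
    stages = {}
    for g, logit in logits.items():
        p = np.exp(logit - denom)
        fit_probs[g] = p.max(axis=1)
        stages[g] = p.argmax(axis=1)
    return (
        pd.DataFrame(fit_probs, index=subject_ids),
        pd.DataFrame(stages, index=subject_ids),
    )


@dataclass
class CrossoverReport:
    chance_level: float
    stages: np.ndarray          # populated stages, ascending
    mean_subtype1_probability: np.ndarray
    crossed: bool
    crossing_stages: list[int]
    empty_stages: list[int]


def detect_crossover(
    assignments: list[SubjectAssignment], k_subtypes: int
) -> CrossoverReport:
    """Flag subtype-probability curves that cross chance level after stage 1.

    The mean subtype-1 posterior probability is traced across assigned
    stages; a crossing of 1/k between consecutive populated stages, landing
    after stage 1, is tagged as a crossover event (possible discontinuity
    between subtypes).  Stages with no subjects are skipped and reported.
    """
    if k_subtypes < 2:
        raise ValueError("crossover detection needs k >= 2 subtypes")
    chance = 1.0 / k_subtypes
    n_stages = assignments[0].stage_posterior.shape[0]
    by_stage: dict[int, list[float]] = {}
    for a in assignments:
        by_stage.setdefault(a.ml_stage, []).append(a.subtype_posterior[0])
    stages = np.array(sorted(by_stage))
    curve = np.array([np.mean(by_stage[k]) for k in stages])
    empty = [k for k in range(n_stages) if k not in by_stage]
    crossing = []
    for (k0, v0), (k1, v1) in zip(zip(stages, curve), zip(stages[1:], curve[1:])):
        if (v0 - chance) * (v1 - chance) < 0 and k1 > 1:
            crossing.append(int(k1))
    return CrossoverReport(
        chance, stages, curve, bool(crossing), crossing, empty
    )
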