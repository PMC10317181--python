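"""Sequence and subtype fitting.

Fitting proceeds in three layers:

* a single progression sequence is fit by multi-start greedy coordinate
  ascent on the stage-marginal data log likelihood (each event in turn is
  relocated to its best valid position until a full sweep yields no
  improvement);
* uncertainty in a fitted sequence is quantified with a Metropolis-Hastings
  chain whose proposal relocates one uniformly chosen event to a uniformly
  chosen valid position;
* C > 1 subtypes are fit hierarchically: the best (C-1)-subtype model is
  split by trying random bipartitions of each cluster, refitting a sequence
  on each side, and polishing with hard-assignment EM (reassign subjects to
  their maximum-probability subtype, refit each subtype's sequence, update
  mixture fractions).

The number of subtypes is selected with the cross-validation information
criterion: CVIC(C) = -2 x the total held-out log likelihood over 10
stratified folds, integrating over the MCMC sequence samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .progression import (
    EventSequence,
    EventSet,
    SubtypeModel,
    log_probability_tensor,
    random_valid_sequence,
)
from .score_model import ScoreProbabilityTensor


@dataclass
class FitConfig:
    """Tunable fitting parameters.

    Defaults are sized for a full cohort run; recovery experiments and the
    test-suite use smaller explicit values.
    """

    n_starts: int = 25
    mcmc_iterations: int = 10_000
    burn_in_fraction: float = 0.2
    max_stored_samples: int = 1_000
    em_max_iter: int = 100
    em_tol: float = 1e-6
    n_folds: int = 10
    n_split_starts: int = 5
    empty_cluster_retries: int = 3
    max_greedy_sweeps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_starts", "mcmc_iterations", "em_max_iter", "n_folds",
                     "n_split_starts", "max_greedy_sweeps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# fast internal objective on raw order arrays


def _stage_ll(logp: np.ndarray, order: np.ndarray) -> np.ndarray:
    """(S, M+1) log stage-conditional likelihood for a raw order array."""
    base = logp[:, :, 0].sum(axis=1)
    r, s = order[:, 0], order[:, 1]
    delta = logp[:, r, s] - logp[:, r, s - 1]
    out = np.empty((logp.shape[0], order.shape[0] + 1))
    out[:, 0] = base
    out[:, 1:] = base[:, None] + np.cumsum(delta, axis=1)
    return out


def _marginal_ll(logp: np.ndarray, order: np.ndarray) -> np.ndarray:
    """(S,) log stage-marginal likelihood per subject, uniform stage prior."""
    mat = _stage_ll(logp, order)
    return logsumexp(mat, axis=1) - np.log(order.shape[0] + 1)


def _objective(logp: np.ndarray, order: np.ndarray) -> float:
    return float(_marginal_ll(logp, order).sum())


def _objective_batch(logp: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """Marginal-likelihood objective for a batch of candidate orders.

    ``orders`` has shape (B, M, 2); returns (B,).  One fancy-indexed gather
    replaces B separate evaluations, which dominates greedy-ascent cost.
    """
    S = logp.shape[0]
    flat = logp.reshape(S, -1)  # (S, R*4)
    n_levels = logp.shape[2]
    cur = orders[:, :, 0] * n_levels + orders[:, :, 1]      # (B, M)
    prev = cur - 1
    delta = flat[:, cur] - flat[:, prev]                     # (S, B, M)
    base = logp[:, :, 0].sum(axis=1)                         # (S,)
    mats = np.concatenate(
        [
            np.zeros((S, orders.shape[0], 1)),
            np.cumsum(delta, axis=2),
        ],
        axis=2,
    ) + base[:, None, None]
    M1 = orders.shape[1] + 1
    return logsumexp(mats, axis=2).sum(axis=0) - S * np.log(M1)


def _relocation_bounds(order: np.ndarray, i: int) -> tuple[np.ndarray, int, int]:
    """Remove event i; return (remaining order, lo, hi) insertion bounds.

    Valid insertion indices j satisfy lo <= j <= hi: the event must stay
    after its region's previous level and before its next level.
    """
    r, s = order[i]
    rest = np.delete(order, i, axis=0)
    same_region = np.nonzero(rest[:, 0] == r)[0]
    lo, hi = 0, rest.shape[0]
    for j in same_region:
        if rest[j, 1] == s - 1:
            lo = j + 1
        elif rest[j, 1] == s + 1:
            hi = min(hi, j)
    return rest, lo, hi


def _greedy_ascent(
    logp: np.ndarray, order: np.ndarray, max_sweeps: int
) -> tuple[np.ndarray, float]:
    """Relocate each event to its best valid position until converged.

    Ties are broken toward the earliest position (argmax over positions in
    ascending order returns the first maximiser).
    """
    order = order.copy()
    best = _objective(logp, order)
    M = order.shape[0]
    events = [tuple(e) for e in order]
    for _ in range(max_sweeps):
        improved = False
        for ev in events:
            i = next(
                k for k in range(M) if order[k, 0] == ev[0] and order[k, 1] == ev[1]
            )
            rest, lo, hi = _relocation_bounds(order, i)
            candidates = np.stack([
                np.insert(rest, j, ev, axis=0) for j in range(lo, hi + 1)
            ])
            scores = _objective_batch(logp, candidates)
            j_best = int(np.argmax(scores))
            if scores[j_best] > best + 1e-12:
                order = np.insert(rest, lo + j_best, ev, axis=0)
                best = scores[j_best]
                improved = True
        if not improved:
            break
    return order, best


def fit_single_sequence(
    probs: ScoreProbabilityTensor,
    event_set: EventSet,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EventSequence, float]:
    """Best sequence over ``n_starts`` greedy ascents from random starts."""
    config = config or FitConfig()
    rng = rng if rng is not None else config.rng()
    logp = log_probability_tensor(probs)
    return _fit_single(logp, event_set, config, rng)


def _fit_single(
    logp: np.ndarray,
    event_set: EventSet,
    config: FitConfig,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> tuple[EventSequence, float]:
    best_order, best_ll = None, -np.inf
    starts = []
    if init is not None:
        starts.append(init.copy())
    while len(starts) < config.n_starts:
        starts.append(random_valid_sequence(event_set, rng).order)
    for start in starts:
        order, ll = _greedy_ascent(logp, start, config.max_greedy_sweeps)
        if ll > best_ll:
            best_order, best_ll = order, ll
    return EventSequence(event_set, best_order), best_ll


# ---------------------------------------------------------------------------
# MCMC


def mcmc_sample_sequences(
    probs: ScoreProbabilityTensor,
    start_seq: EventSequence,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    log_other: np.ndarray | None = None,
    log_fraction: float = 0.0,
) -> tuple[list[EventSequence], np.ndarray]:
    """Metropolis-Hastings over valid sequences.

    The target is the dataset log likelihood under the sequence (uniform
    stage prior).  When sampling one subtype of a mixture, ``log_other``
    carries each subject's fixed log likelihood contribution from the other
    subtypes and ``log_fraction`` the log mixture weight of the varying one.

    Returns the thinned post-burn-in samples and the event x position
    frequency matrix (rows sum to 1) that backs positional variance
    diagrams.
    """
    config = config or FitConfig()
    rng = rng if rng is not None else config.rng()
    logp = log_probability_tensor(probs)
    samples = _mcmc(logp, start_seq, config, rng, log_other, log_fraction)
    density = positional_density(start_seq.event_set, samples)
    return samples, density


def _chain_ll(
    logp: np.ndarray,
    order: np.ndarray,
    log_other: np.ndarray | None,
    log_fraction: float,
) -> float:
    marg = _marginal_ll(logp, order) + log_fraction
    if log_other is not None:
        marg = np.logaddexp(marg, log_other)
    return float(marg.sum())


def _mcmc(
    logp: np.ndarray,
    start_seq: EventSequence,
    config: FitConfig,
    rng: np.random.Generator,
    log_other: np.ndarray | None = None,
    log_fraction: float = 0.0,
) -> list[EventSequence]:
    event_set = start_seq.event_set
    order = start_seq.order.copy()
    ll = _chain_ll(logp, order, log_other, log_fraction)
    if np.isneginf(ll):
        raise ValueError("zero likelihood at the MCMC start sequence")
    M = order.shape[0]
    n_iter = config.mcmc_iterations
    burn = int(n_iter * config.burn_in_fraction)
    kept = n_iter - burn
    thin = max(1, int(np.ceil(kept / config.max_stored_samples)))
    samples: list[EventSequence] = []

    # hoisted invariants for the per-iteration likelihood
    S = logp.shape[0]
    n_levels = logp.shape[2]
    flat = np.ascontiguousarray(logp.reshape(S, -1))
    base = logp[:, :, 0].sum(axis=1)
    log_m1 = np.log(M + 1)
    mat = np.empty((S, M + 1))

    def chain_ll(ord_arr: np.ndarray) -> float:
        cur = ord_arr[:, 0] * n_levels + ord_arr[:, 1]
        delta = flat[:, cur] - flat[:, cur - 1]
        mat[:, 0] = base
        np.cumsum(delta, axis=1, out=mat[:, 1:])
        mat[:, 1:] += base[:, None]
        m = mat.max(axis=1)
        marg = m + np.log(np.exp(mat - m[:, None]).sum(axis=1)) - log_m1
        marg += log_fraction
        if log_other is not None:
            marg = np.logaddexp(marg, log_other)
        return float(marg.sum())

    events = rng.integers(M, size=n_iter)
    unif = rng.random(n_iter)
    log_accept = np.log(rng.random(n_iter))
    for it in range(n_iter):
        i = int(events[it])
        ev = order[i].copy()
        rest, lo, hi = _relocation_bounds(order, i)
        j = lo + int(unif[it] * (hi - lo + 1))
        cand = np.insert(rest, j, ev, axis=0)
        cand_ll = chain_ll(cand)
        if log_accept[it] < cand_ll - ll:
            order, ll = cand, cand_ll
        if it >= burn and (it - burn) % thin == 0:
            samples.append(EventSequence(event_set, order.copy()))
    return samples


def positional_density(
    event_set: EventSet, samples: list[EventSequence]
) -> np.ndarray:
    """(M, M) frequency of each event (row, canonical order) per position."""
    M = event_set.n_events
    counts = np.zeros((M, M))
    L = event_set.max_score
    for seq in samples:
        for pos, (r, s) in enumerate(seq.order):
            counts[r * L + (s - 1), pos] += 1
    if samples:
        counts /= len(samples)
    return counts


# ---------------------------------------------------------------------------
# subtype fitting


class EmptyClusterError(RuntimeError):
    """A subtype lost all members during EM despite re-seeded splits."""


def _hard_assign(per_c_ll: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """argmax_c f_c * L_c per subject (ties -> lower subtype index)."""
    with np.errstate(divide="ignore"):
        scores = per_c_ll + np.log(fractions)[None, :]
    return np.argmax(scores, axis=1)


def _mixture_total(per_c_ll: np.ndarray, fractions: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        return float(
            logsumexp(per_c_ll + np.log(fractions)[None, :], axis=1).sum()
        )


def fit_subtypes(
    probs: ScoreProbabilityTensor,
    event_set: EventSet,
    n_subtypes: int,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    run_mcmc: bool = True,
    group_label: str = "",
) -> SubtypeModel:
    """Fit a C-subtype mixture of progression sequences.

    C = 1 delegates to single-sequence fitting.  C > 1 builds on the fitted
    (C-1)-subtype model by hierarchical split-and-refit followed by EM
    polishing; subtypes are reported sorted by descending mixture fraction.
    """
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be >= 1")
    config = config or FitConfig()
    rng = rng if rng is not None else config.rng()
    logp = log_probability_tensor(probs)
    model = _fit_subtypes_logp(logp, event_set, n_subtypes, config, rng)
    model.group_label = group_label
    if run_mcmc:
        _attach_mcmc(logp, model, config, rng)
    return model


def _fit_subtypes_logp(
    logp: np.ndarray,
    event_set: EventSet,
    C: int,
    config: FitConfig,
    rng: np.random.Generator,
) -> SubtypeModel:
    if C == 1:
        seq, ll = _fit_single(logp, event_set, config, rng)
        return SubtypeModel(event_set, [seq], np.array([1.0]),
                            log_likelihood=ll)

    parent = _fit_subtypes_logp(logp, event_set, C - 1, config, rng)
    parent_ll = np.stack(
        [_marginal_ll(logp, s.order) for s in parent.sequences], axis=1
    )
    parent_assign = _hard_assign(parent_ll, parent.fractions)

    # greedy sub-fits inside splits use a single start from the parent seq
    sub_cfg = replace(config, n_starts=1)
    best_model: SubtypeModel | None = None
    best_ll = -np.inf
    for split_c in range(C - 1):
        members = np.nonzero(parent_assign == split_c)[0]
        if members.size < 2:
            continue
        for _ in range(config.n_split_starts):
            cand = _try_split(
                logp, event_set, parent, split_c, members, sub_cfg, config, rng
            )
            if cand is not None and cand.log_likelihood > best_ll:
                best_model, best_ll = cand, cand.log_likelihood
    if best_model is None:
        raise EmptyClusterError(
            f"could not split the {C - 1}-subtype model into {C} subtypes"
        )
    order = np.argsort(-best_model.fractions, kind="stable")
    return SubtypeModel(
        event_set,
        [best_model.sequences[i] for i in order],
        best_model.fractions[order],
        log_likelihood=best_model.log_likelihood,
    )


def _try_split(
    logp, event_set, parent, split_c, members, sub_cfg, config, rng
) -> SubtypeModel | None:
    """One random bipartition of cluster ``split_c`` + EM polish."""
    for _ in range(config.empty_cluster_retries):
        mask = rng.random(members.size) < 0.5
        if mask.sum() in (0, members.size):
            continue
        a, b = members[mask], members[~mask]
        seq_a, _ = _fit_single(logp[a], event_set, sub_cfg, rng,
                               init=parent.sequences[split_c].order)
        seq_b, _ = _fit_single(logp[b], event_set, sub_cfg, rng,
                               init=parent.sequences[split_c].order)
        sequences = [
            s for i, s in enumerate(parent.sequences) if i != split_c
        ] + [seq_a, seq_b]
        # initial hard assignment: unchanged clusters keep their members,
        # the split cluster's members follow the bipartition
        C = len(sequences)
        remap = {}
        new_c = 0
        for c in range(C - 1):
            if c != split_c:
                remap[c] = new_c
                new_c += 1
        parent_ll = np.stack(
            [_marginal_ll(logp, s.order) for s in parent.sequences], axis=1
        )
        parent_assign = _hard_assign(parent_ll, parent.fractions)
        assign = np.array([remap.get(c, 0) for c in parent_assign])
        assign[a] = C - 2
        assign[b] = C - 1
        return _em_polish(logp, event_set, sequences, assign, sub_cfg, rng)
    return None


def _em_polish(
    logp, event_set, sequences, assign, sub_cfg, rng
) -> SubtypeModel:
    """Hard-assignment EM from an initial cluster assignment.

    Alternates per-cluster sequence refits, fraction updates, and
    maximum-probability reassignment.  Fractions are add-one-smoothed
    cluster shares, (count_c + 1) / (S + C): the standard regularised
    multinomial estimate, so a cluster that loses all members keeps its
    last sequence at a small but nonzero weight and a mixture the data
    cannot support degrades gracefully toward the (C-1)-subtype solution
    instead of failing.
    """
    C = len(sequences)
    S = logp.shape[0]
    sequences = list(sequences)
    prev = -np.inf
    total = -np.inf
    fractions = np.full(C, 1.0 / C)
    for _ in range(sub_cfg.em_max_iter):
        counts = np.bincount(assign, minlength=C)
        fractions = (counts + 1.0) / (S + C)
        for c in range(C):
            idx = np.nonzero(assign == c)[0]
            if idx.size == 0:
                continue
            seq, _ = _fit_single(logp[idx], event_set, sub_cfg, rng,
                                 init=sequences[c].order)
            sequences[c] = seq
        per_c = np.stack(
            [_marginal_ll(logp, s.order) for s in sequences], axis=1
        )
        total = _mixture_total(per_c, fractions)
        if abs(total - prev) < sub_cfg.em_tol:
            break
        prev = total
        assign = _hard_assign(per_c, fractions)
    return SubtypeModel(event_set, sequences, fractions, log_likelihood=total)


def _attach_mcmc(
    logp: np.ndarray,
    model: SubtypeModel,
    config: FitConfig,
    rng: np.random.Generator,
) -> None:
    """Run a per-subtype MH chain under the full mixture likelihood.

    The chain for subtype c varies only that subtype's sequence; the other
    sequences and the fractions stay fixed, so each chain samples the
    conditional posterior of one sequence given all the data.  A component
    the data barely use (a near-zero fraction after a degenerate split)
    is then barely constrained and its chain explores widely — which is
    the correct statement of that model's uncertainty, and the mechanism
    by which held-out evaluation (integrating over these samples)
    penalises a mixture carrying a redundant component.
    """
    C = model.n_subtypes
    per_c = np.stack(
        [_marginal_ll(logp, s.order) for s in model.sequences], axis=1
    )
    with np.errstate(divide="ignore"):
        logf = np.log(model.fractions)
    model.mcmc_samples = []
    for c in range(C):
        if C > 1:
            others = logsumexp(
                np.delete(per_c + logf[None, :], c, axis=1), axis=1
            )
        else:
            others = None
        samples = _mcmc(
            logp, model.sequences[c], config, rng,
            log_other=others, log_fraction=float(logf[c]),
        )
        model.mcmc_samples.append(samples)


# ---------------------------------------------------------------------------
# cross-validation / CVIC


@dataclass
class CVICResult:
    cvic: np.ndarray           # indexed by C-1
    selected: int              # argmin CVIC (1-based C)
    fold_loglik: np.ndarray    # (C_max, n_folds) held-out log likelihoods
    folds: list[np.ndarray]    # test-subject indices per fold


def stage_stratified_folds(
    stages: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition subjects into folds stratified by stage tertile."""
    S = stages.shape[0]
    if not 2 <= n_folds <= S:
        raise ValueError(f"n_folds must be in [2, {S}]")
    q = np.quantile(stages, [1 / 3, 2 / 3])
    strata = np.digitize(stages, q)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for stratum in np.unique(strata):
        idx = np.nonzero(strata == stratum)[0]
        rng.shuffle(idx)
        for i, subject in enumerate(idx):
            folds[(offset + i) % n_folds].append(subject)
        offset += idx.size
    out = [np.array(sorted(f), dtype=int) for f in folds]
    if any(f.size == 0 for f in out):
        raise ValueError("a fold has zero test subjects")
    return out


def heldout_log_likelihood(
    logp_test: np.ndarray, model: SubtypeModel
) -> float:
    """Held-out log likelihood integrating over MCMC sequence samples.

    Each subtype's subject likelihood is averaged over that subtype's
    posterior sequence samples, then combined with the mixture fractions.
    Falls back to the point sequences if a subtype has no samples.
    """
    per_c = []
    for c, seq in enumerate(model.sequences):
        chain = model.mcmc_samples[c] if model.mcmc_samples else []
        if chain:
            stack = np.stack(
                [_marginal_ll(logp_test, s.order) for s in chain], axis=0
            )
            per_c.append(logsumexp(stack, axis=0) - np.log(len(chain)))
        else:
            per_c.append(_marginal_ll(logp_test, seq.order))
    per_c = np.stack(per_c, axis=1)
    return _mixture_total(per_c, model.fractions)


def cross_validate_cvic(
    probs: ScoreProbabilityTensor,
    event_set: EventSet,
    C_max: int,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CVICResult:
    """CVIC(C) for C = 1..C_max; the selected C minimises CVIC."""
    if C_max < 1:
        raise ValueError("C_max must be >= 1")
    config = config or FitConfig()
    rng = rng if rng is not None else config.rng()
    logp = log_probability_tensor(probs)
    S = logp.shape[0]

    # preliminary single-sequence staging for fold stratification
    seq0, _ = _fit_single(logp, event_set, config, rng)
    stages = np.argmax(_stage_ll(logp, seq0.order), axis=1)
    folds = stage_stratified_folds(stages, config.n_folds, rng)

    fold_ll = np.zeros((C_max, len(folds)))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(S), test_idx)
        logp_train, logp_test = logp[train_idx], logp[test_idx]
        # chains for every candidate C share one random stream per fold
        # (common random numbers): chain noise then largely cancels in the
        # CVIC(C) - CVIC(C') comparison instead of masking it
        chain_seed = int(rng.integers(2**31))
        for C in range(1, C_max + 1):
            model = _fit_subtypes_logp(logp_train, event_set, C, config, rng)
            _attach_mcmc(logp_train, model, config,
                         np.random.default_rng(chain_seed))
            fold_ll[C - 1, f] = heldout_log_likelihood(logp_test, model)
    cvic = -2.0 * fold_ll.sum(axis=1)
    return CVICResult(cvic, int(np.argmin(cvic)) + 1, fold_ll, folds)
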