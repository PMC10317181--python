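"""Ordinal event-based progression model.

Disease progression is modelled as a sequence of events, each event being a
region reaching a new integer score level.  With R regions and score levels
1..3 there are M = 3R events and M+1 stages: at stage k the first k events
of the sequence have occurred, and each region sits at the highest level it
has reached so far (level 0 before its first event).  A sequence is valid
when, for every region, the level-s event precedes the level-(s+1) event.

The subject likelihood at stage k is the product over regions of the
probability (from the score kernel) that the region is at its implied
level.  Marginalising k over a stage prior gives the subject likelihood
under one sequence; a mixture over subtype sequences with fractions f_c
gives the full dataset likelihood.

All likelihood work happens in log space.  Probabilities are floored at
1e-250 before taking logs so that deterministic inputs (hard-assigned or
noiseless) cannot produce NaNs; the floor is far below any probability the
kernel itself produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .score_model import ScoreProbabilityTensor

PROB_FLOOR = 1e-250

#: cap on M for exhaustive sequence enumeration
ENUMERATION_LIMIT = 10


class SequenceError(ValueError):
    """Invalid event sequence."""


@dataclass(frozen=True)
class EventSet:
    """All (region, level) events for a region list and maximum score level.

    Events are indexed region-major: region r's level-s event has index
    r * max_score + (s - 1).  M = n_regions * max_score is the number of
    nonzero stages.
    """

    region_names: tuple[str, ...]
    max_score: int = 3

    def __post_init__(self) -> None:
        if len(self.region_names) == 0:
            raise ValueError("empty region list")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("duplicate region names")
        if self.max_score < 1:
            raise ValueError(f"max_score must be >= 1, got {self.max_score}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_events(self) -> int:
        return self.n_regions * self.max_score

    @property
    def events(self) -> np.ndarray:
        """(M, 2) array of (region_index, level) rows, region-major."""
        r = np.repeat(np.arange(self.n_regions), self.max_score)
        s = np.tile(np.arange(1, self.max_score + 1), self.n_regions)
        return np.column_stack([r, s])


def build_event_set(regions, max_score: int = 3) -> EventSet:
    """Event space over ``regions`` with levels 1..max_score."""
    return EventSet(tuple(regions), max_score)


@dataclass(frozen=True)
class EventSequence:
    """A valid ordering of an EventSet's events; houses the stage axis 0..M."""

    event_set: EventSet
    order: np.ndarray  # (M, 2) int array of (region_index, level) rows

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=int)
        object.__setattr__(self, "order", order)
        es = self.event_set
        if order.shape != (es.n_events, 2):
            raise SequenceError(
                f"expected {es.n_events} events, got shape {order.shape}"
            )
        seen = set(map(tuple, order))
        expected = set(map(tuple, es.events))
        if seen != expected:
            raise SequenceError("sequence is not a permutation of the event set")
        if not _levels_ordered(order, es.n_regions):
            raise SequenceError("level-ordering constraint violated")

    @property
    def n_stages(self) -> int:
        return self.event_set.n_events + 1

    def implied_levels(self) -> np.ndarray:
        """(M+1, R) array: each region's level at every stage."""
        es = self.event_set
        levels = np.zeros((es.n_events + 1, es.n_regions), dtype=int)
        for k, (r, s) in enumerate(self.order, start=1):
            levels[k] = levels[k - 1]
            levels[k, r] = s
        return levels

    def tokens(self) -> list[str]:
        """Serialise as 'region:level' tokens."""
        names = self.event_set.region_names
        return [f"{names[r]}:{s}" for r, s in self.order]

    @classmethod
    def from_tokens(cls, event_set: EventSet, tokens) -> "EventSequence":
        index = {name: i for i, name in enumerate(event_set.region_names)}
        rows = []
        for tok in tokens:
            name, _, lvl = tok.rpartition(":")
            rows.append((index[name], int(lvl)))
        return cls(event_set, np.array(rows))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventSequence)
            and self.event_set == other.event_set
            and np.array_equal(self.order, other.order)
        )

    def __hash__(self) -> int:
        return hash((self.event_set, self.order.tobytes()))


def _levels_ordered(order: np.ndarray, n_regions: int) -> bool:
    last = np.zeros(n_regions, dtype=int)
    for r, s in order:
        if s != last[r] + 1:
            return False
        last[r] = s
    return True


@dataclass
class SubtypeModel:
    """Fitted progression model: one sequence per subtype plus mixture weights.

    ``mcmc_samples[c]`` holds posterior sequence samples for subtype c (may
    be empty before sampling); ``fractions`` sum to 1.
    """

    event_set: EventSet
    sequences: list[EventSequence]
    fractions: np.ndarray
    mcmc_samples: list[list[EventSequence]] = field(default_factory=list)
    group_label: str = ""
    log_likelihood: float = np.nan

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.sequences) != len(self.fractions):
            raise ValueError("one fraction per subtype required")
        if not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("subtype fractions must sum to 1")
        if not self.mcmc_samples:
            self.mcmc_samples = [[] for _ in self.sequences]

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "regions": list(self.event_set.region_names),
            "max_score": self.event_set.max_score,
            "fractions": self.fractions.tolist(),
            "sequences": [seq.tokens() for seq in self.sequences],
            "log_likelihood": float(self.log_likelihood),
            "mcmc_samples": [
                [s.tokens() for s in samples] for samples in self.mcmc_samples
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SubtypeModel":
        es = build_event_set(payload["regions"], payload["max_score"])
        seqs = [EventSequence.from_tokens(es, t) for t in payload["sequences"]]
        samples = [
            [EventSequence.from_tokens(es, t) for t in chain]
            for chain in payload.get("mcmc_samples", [])
        ]
        return cls(
            es,
            seqs,
            np.array(payload["fractions"]),
            samples,
            payload.get("group_label", ""),
            payload.get("log_likelihood", np.nan),
        )


# ---------------------------------------------------------------------------
# likelihoods


def log_probability_tensor(probs: ScoreProbabilityTensor) -> np.ndarray:
    """Floored elementwise log of the score-probability tensor."""
    return np.log(np.clip(probs.probs, PROB_FLOOR, None))


def stage_log_likelihood_matrix(
    logp: np.ndarray, seq: EventSequence
) -> np.ndarray:
    """(S, M+1) matrix of log stage-conditional subject likelihoods.

    Computed incrementally: stage 0 is the all-level-0 product; event k
    moves one region from level s-1 to s, multiplying the likelihood by the
    corresponding probability ratio.
    """
    order = seq.order
    base = logp[:, :, 0].sum(axis=1)  # (S,)
    r, s = order[:, 0], order[:, 1]
    delta = logp[:, r, s] - logp[:, r, s - 1]  # (S, M)
    out = np.empty((logp.shape[0], order.shape[0] + 1))
    out[:, 0] = base
    out[:, 1:] = base[:, None] + np.cumsum(delta, axis=1)
    return out


def _uniform_prior(n_stages: int) -> np.ndarray:
    return np.full(n_stages, 1.0 / n_stages)


def _check_prior(stage_prior, n_stages: int) -> np.ndarray:
    if stage_prior is None:
        return _uniform_prior(n_stages)
    prior = np.asarray(stage_prior, dtype=float)
    if prior.shape != (n_stages,):
        raise ValueError(f"stage prior must have length {n_stages}")
    if not np.isclose(prior.sum(), 1.0):
        raise ValueError("stage prior must sum to 1")
    return prior


def stage_conditional_likelihood(
    probs: ScoreProbabilityTensor, seq: EventSequence, subject, k: int
) -> float:
    """P(subject's data | sequence, stage k): product over regions."""
    if not 0 <= k <= seq.event_set.n_events:
        raise ValueError(f"stage {k} outside 0..{seq.event_set.n_events}")
    i = probs.subject_ids.index(subject)
    logp = log_probability_tensor(probs)
    return float(np.exp(stage_log_likelihood_matrix(logp[[i]], seq)[0, k]))


def subject_marginal_likelihood(
    probs: ScoreProbabilityTensor,
    seq: EventSequence,
    subject,
    stage_prior=None,
) -> float:
    """Stage-marginal subject likelihood: sum_k prior_k * P(data | k)."""
    prior = _check_prior(stage_prior, seq.n_stages)
    i = probs.subject_ids.index(subject)
    logp = log_probability_tensor(probs)
    row = stage_log_likelihood_matrix(logp[[i]], seq)[0]
    return float(np.exp(logsumexp(row, b=prior)))


def subject_marginal_log_likelihoods(
    logp: np.ndarray, seq: EventSequence, stage_prior=None
) -> np.ndarray:
    """(S,) vector of log stage-marginal likelihoods under one sequence."""
    prior = _check_prior(stage_prior, seq.n_stages)
    mat = stage_log_likelihood_matrix(logp, seq)
    return logsumexp(mat + np.log(prior)[None, :], axis=1)


def mixture_log_likelihoods(
    logp: np.ndarray, model: SubtypeModel, stage_prior=None
) -> np.ndarray:
    """(S,) per-subject log likelihood under the subtype mixture."""
    per_c = np.stack(
        [subject_marginal_log_likelihoods(logp, seq, stage_prior)
         for seq in model.sequences],
        axis=1,
    )  # (S, C)
    with np.errstate(divide="ignore"):
        logf = np.log(model.fractions)
    return logsumexp(per_c + logf[None, :], axis=1)


def dataset_log_likelihood(
    probs: ScoreProbabilityTensor, model: SubtypeModel, stage_prior=None
) -> float:
    """Total log likelihood of the cohort under a subtype mixture model."""
    logp = log_probability_tensor(probs)
    ll = mixture_log_likelihoods(logp, model, stage_prior)
    if np.isneginf(ll).any():
        bad = [probs.subject_ids[i] for i in np.nonzero(np.isneginf(ll))[0]]
        warnings.warn(f"zero likelihood for subjects {bad}")
        return float("-inf")
    return float(ll.sum())


# ---------------------------------------------------------------------------
# oracle


def enumerate_valid_sequences(event_set: EventSet) -> list[EventSequence]:
    """All valid orderings, by exhaustive recursion.  Guarded at M <= 10.

    Serves as the brute-force oracle against which greedy/MCMC fitting is
    validated on small instances.
    """
    if event_set.n_events > ENUMERATION_LIMIT:
        raise ValueError(
            f"M = {event_set.n_events} > {ENUMERATION_LIMIT}: enumeration "
            "would explode"
        )
    R, L = event_set.n_regions, event_set.max_score
    results: list[EventSequence] = []
    order: list[tuple[int, int]] = []
    placed = np.zeros(R, dtype=int)  # highest level placed per region

    def recurse() -> None:
        if len(order) == event_set.n_events:
            results.append(EventSequence(event_set, np.array(order)))
            return
        for r in range(R):
            if placed[r] < L:
                placed[r] += 1
                order.append((r, placed[r]))
                recurse()
                order.pop()
                placed[r] -= 1

    recurse()
    return results


def random_valid_sequence(event_set: EventSet, rng: np.random.Generator) -> EventSequence:
    """Sample a random valid ordering (uniform among available events)."""
    R, L = event_set.n_regions, event_set.max_score
    placed = np.zeros(R, dtype=int)
    order = []
    for _ in range(event_set.n_events):
        avail = np.nonzero(placed < L)[0]
        r = rng.choice(avail)
        placed[r] += 1
        order.append((r, placed[r]))
    return EventSequence(event_set, np.array(order))
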