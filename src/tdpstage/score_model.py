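"""Translate ordinal ratings into per-score-level probabilities.

The event-based likelihood consumes, for every subject and region, a
probability distribution over the integer score levels {0, 1, 2, 3}.  A
rating r maps to P(level = z) proportional to a Gaussian density centred at
r with standard deviation sigma (default 0.5) evaluated at each z, then
normalised across the four levels.  The half-point "sparse" rating of 0.5
therefore gives equal probability to levels 0 and 1.  Missing ratings get a
uniform distribution over the four levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RegionalScoreTable

#: integer score levels the model stages over
SCORE_LEVELS = np.array([0.0, 1.0, 2.0, 3.0])


@dataclass
class ScoreProbabilityTensor:
    """P(true level | rating) per subject x region x level.

    probs[s, r, z] is the probability subject s's region r is truly at level
    z in {0,1,2,3}; every (s, r) slice sums to 1.
    """

    probs: np.ndarray  # (n_subjects, n_regions, 4)
    subject_ids: list
    region_names: list[str]
    sigma: float = 0.5

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("probability slices do not sum to 1")
        if (self.probs < 0).any() or (self.probs > 1).any():
            raise ValueError("probabilities outside [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.probs.shape[0]

    @property
    def n_regions(self) -> int:
        return self.probs.shape[1]

    def subset(self, indices) -> "ScoreProbabilityTensor":
        idx = np.asarray(indices)
        return ScoreProbabilityTensor(
            self.probs[idx],
            [self.subject_ids[i] for i in idx],
            self.region_names,
            self.sigma,
        )


def rating_to_distribution(
    rating: float, sigma: float = 0.5, hard_zero: bool = False
) -> np.ndarray:
    """Distribution over {0,1,2,3} for a single rating (NaN -> uniform)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if np.isnan(rating):
        return np.full(4, 0.25)
    if hard_zero and rating == 0.0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    dens = np.exp(-((SCORE_LEVELS - rating) ** 2) / (2.0 * sigma**2))
    return dens / dens.sum()


def ratings_to_probabilities(
    table: RegionalScoreTable, sigma: float = 0.5, hard_zero: bool = False
) -> ScoreProbabilityTensor:
    """Convert a whole score table to a ScoreProbabilityTensor.

    ``hard_zero=True`` assigns rating 0 deterministically to level 0 instead
    of kernel-converting it; the default treats 0 like every other rating so
    a pristine region still carries a little mass on level 1.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    ratings = table.scores.to_numpy(dtype=float)  # (S, R)
    # density of each rating against each integer level
    dens = np.exp(
        -((ratings[:, :, None] - SCORE_LEVELS[None, None, :]) ** 2)
        / (2.0 * sigma**2)
    )
    missing = np.isnan(ratings)
    dens[missing] = 1.0  # uniform over the four levels
    if hard_zero:
        zero = ~missing & (ratings == 0.0)
        dens[zero] = 0.0
        dens[zero, 0] = 1.0
    probs = dens / dens.sum(axis=2, keepdims=True)
    return ScoreProbabilityTensor(
        probs, table.subject_ids, table.region_names, sigma
    )
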