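"""Synthetic cohort generation.

The raw neuropathology tables the pipeline was designed around are
available only on request, so every pipeline step is exercised on synthetic
cohorts with the same statistical structure: each subject is drawn from a
subtype (by mixture fraction) and a stage (uniform or truncated-geometric,
the latter emulating the under-sampling of late stages in autopsy series),
their true regional score levels follow the subtype's event sequence at
that stage, and observation noise flips a rating to an adjacent point of
the legal scale {0, 0.5, 1, 2, 3} with probability epsilon (the sparse 0.5
rating is reachable from both 0 and 1).  Region-wise missingness and a
linear stage-age model (slope sign configurable: positive for a LATE-like
cohort, negative for an FTLD-like one) complete the metadata.

Observation noise is adjacent-level flipping rather than sampling from the
Gaussian rating kernel the model assumes, a deliberate slight model
mismatch that keeps recovery experiments honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortMetadata, RegionalScoreTable
from .progression import EventSequence, EventSet, build_event_set

#: canonical 21-region sampling battery
REGIONS_21 = (
    "amygdala",
    "dentate_gyrus",
    "ca_subiculum",
    "entorhinal_cortex",
    "anterior_cingulate",
    "superior_middle_temporal",
    "middle_frontal",
    "angular_gyrus",
    "occipital_cortex",
    "thalamus",
    "globus_pallidus",
    "caudate_putamen",
    "substantia_nigra",
    "midbrain",
    "locus_coeruleus",
    "pons",
    "cerebellum",
    "medulla",
    "orbitofrontal_cortex",
    "motor_cortex",
    "spinal_cord",
)

#: adjacency on the legal rating scale; noise flips move one step
_SCALE = np.array([0.0, 0.5, 1.0, 2.0, 3.0])


def staircase_sequence(
    event_set: EventSet, region_order, stagger: int | None = None
) -> EventSequence:
    """Interleaved progression: region i's level-s event fires at rank
    position(i) + (s-1)*stagger, so early regions worsen while later
    regions are still catching up.  Valid by construction."""
    names = list(event_set.region_names)
    order_idx = [names.index(r) for r in region_order]
    if sorted(order_idx) != list(range(len(names))):
        raise ValueError("region_order must be a permutation of the regions")
    if stagger is None:
        stagger = max(1, len(names) // 2)
    rank = {r: i for i, r in enumerate(order_idx)}
    events = [
        (r, s)
        for r in range(event_set.n_regions)
        for s in range(1, event_set.max_score + 1)
    ]
    events.sort(key=lambda ev: (rank[ev[0]] + (ev[1] - 1) * stagger,
                                rank[ev[0]], ev[1]))
    return EventSequence(event_set, np.array(events))


@dataclass
class GeneratorConfig:
    """Ground-truth structure of one synthetic cohort."""

    region_names: tuple[str, ...]
    sequences: list[EventSequence]
    fractions: tuple[float, ...]
    n_subjects: int
    group_label: str = "synthetic"
    stage_distribution: str = "truncated_geometric"  # or "uniform"
    stage_geometric_p: float = 0.08
    noise_epsilon: float = 0.1
    missingness: dict = field(default_factory=dict)  # region -> rate
    default_missingness: float = 0.0
    # linear stage-age model: age_at_death = intercept + slope*stage + noise
    age_intercept: float = 70.0
    age_slope: float = 0.0
    age_sd: float = 8.0
    duration_mean: float = 7.0
    duration_sd: float = 3.0
    female_fraction: float = 0.5
    pmi_mean: float = 12.5
    pmi_sd: float = 6.0
    braak_mean: float = 2.0
    apoe_e4_rate: float = 0.25
    apoe_e2_rate: float = 0.12
    tdp_types: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("subtype fractions must sum to 1")
        if len(self.fractions) != len(self.sequences):
            raise ValueError("one fraction per sequence required")
        if not 0.0 <= self.noise_epsilon < 0.5:
            raise ValueError("noise_epsilon must be in [0, 0.5)")
        rates = [self.default_missingness, *self.missingness.values()]
        if any(not 0.0 <= m < 1.0 for m in rates):
            raise ValueError("missingness rates must be in [0, 1)")
        for seq in self.sequences:
            if tuple(seq.event_set.region_names) != tuple(self.region_names):
                raise ValueError("sequence regions do not match config regions")

    @property
    def event_set(self) -> EventSet:
        return self.sequences[0].event_set


def _stage_probabilities(cfg: GeneratorConfig, n_stages: int) -> np.ndarray:
    if cfg.stage_distribution == "uniform":
        return np.full(n_stages, 1.0 / n_stages)
    if cfg.stage_distribution == "truncated_geometric":
        w = (1.0 - cfg.stage_geometric_p) ** np.arange(n_stages)
        return w / w.sum()
    raise ValueError(f"unknown stage distribution {cfg.stage_distribution!r}")


def _flip_adjacent(ratings: np.ndarray, eps: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Perturb each rating to an adjacent scale point with probability eps."""
    idx = np.searchsorted(_SCALE, ratings)  # ratings are exact scale points
    flip = rng.random(ratings.shape) < eps
    direction = np.where(
        idx == 0, 1,
        np.where(idx == len(_SCALE) - 1, -1,
                 np.where(rng.random(ratings.shape) < 0.5, -1, 1)),
    )
    return _SCALE[np.where(flip, idx + direction, idx)]


def generate_cohort(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[RegionalScoreTable, CohortMetadata, pd.DataFrame]:
    """Draw a cohort; returns (score table, metadata, ground truth).

    Ground truth holds each subject's true subtype and stage.  Fully
    reproducible from ``config.seed`` when no generator is passed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    es = config.event_set
    n, R = config.n_subjects, es.n_regions
    n_stages = es.n_events + 1

    subtype = rng.choice(len(config.sequences), size=n, p=config.fractions)
    stage = rng.choice(n_stages, size=n,
                       p=_stage_probabilities(config, n_stages))
    implied = np.stack([seq.implied_levels() for seq in config.sequences])
    true_scores = implied[subtype, stage].astype(float)  # (n, R)

    observed = _flip_adjacent(true_scores, config.noise_epsilon, rng)
    miss_rates = np.array([
        config.missingness.get(r, config.default_missingness)
        for r in es.region_names
    ])
    missing = rng.random((n, R)) < miss_rates[None, :]
    observed = np.where(missing, np.nan, observed)

    ids = [f"{config.group_label}-{i:04d}" for i in range(n)]
    scores = pd.DataFrame(observed, index=pd.Index(ids, name="subject_id"),
                          columns=list(es.region_names))
    groups = pd.Series(config.group_label, index=scores.index, name="group")
    table = RegionalScoreTable(scores, groups)

    age_at_death = (config.age_intercept + config.age_slope * stage
                    + rng.normal(0.0, config.age_sd, n))
    duration = np.clip(
        rng.normal(config.duration_mean, config.duration_sd, n), 0.5, None
    )
    meta = pd.DataFrame(
        {
            "group": config.group_label,
            "age_at_onset": age_at_death - duration,
            "age_at_death": age_at_death,
            "disease_duration": duration,
            "sex": np.where(rng.random(n) < config.female_fraction, "F", "M"),
            "post_mortem_interval": np.clip(
                rng.normal(config.pmi_mean, config.pmi_sd, n), 1.0, None
            ),
            "braak_stage": np.clip(
                np.round(rng.normal(config.braak_mean, 1.5, n)), 0, 6
            ).astype(int),
            "apoe_e2_carrier": rng.random(n) < config.apoe_e2_rate,
            "apoe_e4_carrier": rng.random(n) < config.apoe_e4_rate,
            "tdp_type": (
                rng.choice(config.tdp_types, size=n)
                if config.tdp_types else pd.NA
            ),
        },
        index=scores.index,
    )
    truth = pd.DataFrame(
        {"subtype": subtype, "stage": stage}, index=scores.index
    )
    return table, CohortMetadata(meta), truth


# ---------------------------------------------------------------------------
# presets

_LATE_ORDER = (
    "amygdala", "ca_subiculum", "entorhinal_cortex", "dentate_gyrus",
    "orbitofrontal_cortex", "anterior_cingulate", "superior_middle_temporal",
    "middle_frontal", "angular_gyrus", "thalamus", "caudate_putamen",
    "globus_pallidus", "substantia_nigra", "midbrain", "locus_coeruleus",
    "pons", "medulla", "occipital_cortex", "cerebellum", "motor_cortex",
    "spinal_cord",
)

_ALS_ORDER = (
    "spinal_cord", "medulla", "motor_cortex", "caudate_putamen", "thalamus",
    "globus_pallidus", "midbrain", "substantia_nigra", "pons",
    "anterior_cingulate", "middle_frontal", "angular_gyrus",
    "superior_middle_temporal", "entorhinal_cortex", "amygdala",
    "ca_subiculum", "dentate_gyrus", "occipital_cortex",
    "orbitofrontal_cortex", "locus_coeruleus", "cerebellum",
)

_FTLD_ORDER = (
    "anterior_cingulate", "superior_middle_temporal", "amygdala",
    "entorhinal_cortex", "middle_frontal", "orbitofrontal_cortex",
    "ca_subiculum", "dentate_gyrus", "angular_gyrus", "caudate_putamen",
    "globus_pallidus", "thalamus", "substantia_nigra", "midbrain",
    "occipital_cortex", "motor_cortex", "medulla", "pons", "spinal_cord",
    "locus_coeruleus", "cerebellum",
)

#: regions with elevated missingness per preset; at the default high rate
#: they exceed the 25% exclusion threshold, mirroring typical sampling gaps
_PRESET_SPARSE_REGIONS = {
    "ALS-like": ("occipital_cortex", "locus_coeruleus", "orbitofrontal_cortex"),
    "FTLD-like": ("orbitofrontal_cortex",),
    "LATE-like": ("motor_cortex", "spinal_cord"),
}


def preset(name: str, seed: int = 0) -> GeneratorConfig:
    """Cohort presets for the three proteinopathy-like study groups.

    ALS-like: spinal-cord-first sequence, n = 141, no stage-age trend.
    FTLD-like: cortical-first sequence, n = 126, negative stage-age slope.
    LATE-like: amygdala-first sequence, n = 304, positive stage-age slope.
    Group sizes, mean ages and post-mortem intervals follow the published
    demographics of the corresponding autopsy groups; a few regions carry
    high missingness so the >25% exclusion rule is exercised end-to-end.
    """
    es = build_event_set(REGIONS_21, 3)
    high = 0.35  # sparsely sampled regions: well past the 25% exclusion rule
    if name == "ALS-like":
        cfg = GeneratorConfig(
            region_names=REGIONS_21,
            sequences=[staircase_sequence(es, _ALS_ORDER)],
            fractions=(1.0,),
            n_subjects=141,
            group_label="ALS",
            age_intercept=60.0,
            age_slope=0.0,
            age_sd=10.5,
            duration_mean=4.3,
            duration_sd=2.0,
            female_fraction=0.40,
            braak_mean=1.7,
            seed=seed,
        )
    elif name == "FTLD-like":
        cfg = GeneratorConfig(
            region_names=REGIONS_21,
            sequences=[staircase_sequence(es, _FTLD_ORDER)],
            fractions=(1.0,),
            n_subjects=126,
            group_label="FTLD-TDP",
            age_intercept=76.0,
            age_slope=-0.25,
            age_sd=9.0,
            duration_mean=7.3,
            duration_sd=3.0,
            female_fraction=0.45,
            braak_mean=2.0,
            tdp_types=("A", "B", "C", "E"),
            seed=seed,
        )
    elif name == "LATE-like":
        cfg = GeneratorConfig(
            region_names=REGIONS_21,
            sequences=[staircase_sequence(es, _LATE_ORDER)],
            fractions=(1.0,),
            n_subjects=304,
            group_label="LATE-NC",
            age_intercept=74.0,
            age_slope=0.35,
            age_sd=8.0,
            duration_mean=10.5,
            duration_sd=4.0,
            female_fraction=0.55,
            braak_mean=5.0,
            seed=seed,
        )
    else:
        raise KeyError(f"unknown preset {name!r}")
    cfg = replace(
        cfg,
        missingness={r: high for r in _PRESET_SPARSE_REGIONS[name]},
        default_missingness=0.05,
    )
    return cfg


def restrict_config(cfg: GeneratorConfig, regions) -> GeneratorConfig:
    """Restrict a config to a region subset (order taken from the subset).

    Ground-truth sequences keep their relative event order over the
    retained regions, so the restricted cohort progresses consistently
    with the full one.
    """
    regions = tuple(regions)
    unknown = set(regions) - set(cfg.region_names)
    if unknown:
        raise KeyError(f"regions not in config: {sorted(unknown)}")
    es = build_event_set(regions, cfg.event_set.max_score)
    index = {r: i for i, r in enumerate(regions)}
    new_sequences = []
    for seq in cfg.sequences:
        kept = [
            (index[seq.event_set.region_names[r]], s)
            for r, s in seq.order
            if seq.event_set.region_names[r] in index
        ]
        new_sequences.append(EventSequence(es, np.array(kept)))
    return replace(
        cfg,
        region_names=regions,
        sequences=new_sequences,
        missingness={r: v for r, v in cfg.missingness.items() if r in index},
    )


def three_group_configs(
    n_per_group: int = 100,
    noise_epsilon: float = 0.05,
    seed: int = 0,
    age_informative: bool = False,
) -> dict[str, GeneratorConfig]:
    """Three groups with distinct progression sequences (classifier study).

    Eight shared regions; the group orderings are forward, reversed, and a
    rotation, so each pair differs over most of the stage axis.  Stages are
    uniform over 0..M so classification is assessed along the whole
    trajectory.  With ``age_informative=True`` the first two groups share
    ONE sequence but have well-separated age distributions: regional scores
    alone cannot distinguish them, age can — the construction under which
    the logistic model must beat winner-takes-all.
    """
    regions = tuple(f"R{i}" for i in range(8))
    es = build_event_set(regions, 3)
    orders = {
        "G1": regions,
        "G2": regions if age_informative else tuple(reversed(regions)),
        "G3": regions[3:] + regions[:3],
    }
    ages = {"G1": 58.0, "G2": 82.0, "G3": 70.0} if age_informative else {
        "G1": 70.0, "G2": 70.0, "G3": 70.0
    }
    out = {}
    for i, (label, order) in enumerate(orders.items()):
        out[label] = GeneratorConfig(
            region_names=regions,
            sequences=[staircase_sequence(es, order)],
            fractions=(1.0,),
            n_subjects=n_per_group,
            group_label=label,
            stage_distribution="uniform",
            noise_epsilon=noise_epsilon,
            age_intercept=ages[label],
            age_sd=6.0,
            seed=seed * 101 + i,
        )
    return out


def two_subtype_config(
    region_names=None,
    n_subjects: int = 200,
    fractions: tuple[float, float] = (0.5, 0.5),
    noise_epsilon: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> GeneratorConfig:
    """Two planted subtypes with reversed region orders (recovery tests)."""
    regions = tuple(region_names) if region_names is not None else REGIONS_21[:8]
    es = build_event_set(regions, 3)
    fwd = staircase_sequence(es, regions)
    rev = staircase_sequence(es, tuple(reversed(regions)))
    return GeneratorConfig(
        region_names=regions,
        sequences=[fwd, rev],
        fractions=fractions,
        n_subjects=n_subjects,
        noise_epsilon=noise_epsilon,
        seed=seed,
        **kwargs,
    )
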