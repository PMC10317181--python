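import numpy as np
import pandas as pd
import pytest

from tdpstage.io import RegionalScoreTable
from tdpstage.progression import build_event_set
from tdpstage.score_model import ScoreProbabilityTensor
from tdpstage.synthetic import GeneratorConfig, generate_cohort, staircase_sequence


@pytest.fixture
def small_table() -> RegionalScoreTable:
    df = pd.DataFrame(
        {
            "amygdala": [0.0, 0.5, 3.0],
            "medulla": [1.0, np.nan, 2.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="subject_id"),
    )
    return RegionalScoreTable(df)


@pytest.fixture
def two_region_probs() -> ScoreProbabilityTensor:
    """One subject, two single-level regions: P_r1=(0.2,0.8), P_r2=(0.7,0.3)."""
    p = np.zeros((1, 2, 4))
    p[0, 0] = [0.2, 0.8, 0.0, 0.0]
    p[0, 1] = [0.7, 0.3, 0.0, 0.0]
    return ScoreProbabilityTensor(p, ["s1"], ["r1", "r2"])


@pytest.fixture
def staged_cohort():
    """Noiseless six-region cohort covering every stage uniformly."""
    regions = tuple(f"R{i}" for i in range(6))
    es = build_event_set(regions, 3)
    seq = staircase_sequence(es, regions)
    cfg = GeneratorConfig(
        region_names=regions,
        sequences=[seq],
        fractions=(1.0,),
        n_subjects=4 * (es.n_events + 1),
        stage_distribution="uniform",
        noise_epsilon=0.0,
        seed=5,
    )
    table, meta, truth = generate_cohort(cfg)
    return cfg, table, meta, truth
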