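import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tdpstage.assignment import SubjectAssignment
from tdpstage.io import RegionalScoreTable
from tdpstage.staging import UNCLASSIFIABLE
from tdpstage.stats import (
    benjamini_hochberg,
    classifiable_vs_unclassifiable_test,
    regionwise_subtype_glm,
    stage_association,
)


def _assignments(stages, subtypes=None):
    subtypes = subtypes if subtypes is not None else [0] * len(stages)
    out = []
    for i, (k, c) in enumerate(zip(stages, subtypes)):
        sp = np.zeros(int(max(stages)) + 2)
        sp[k] = 1.0
        out.append(
            SubjectAssignment(f"s{i}", c, int(k), sp, np.array([1.0]), 1.0)
        )
    return out


class TestStageAssociation:
    def test_self_correlation_is_one(self):
        a = _assignments([0, 1, 2, 3, 4])
        values = pd.Series([0, 1, 2, 3, 4], index=[f"s{i}" for i in range(5)])
        r, p = stage_association(a, values)
        assert r == pytest.approx(1.0)

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(0)
        stages = rng.integers(0, 20, 30)
        values = stages * 0.4 + rng.normal(0, 2, 30)
        a = _assignments(stages)
        series = pd.Series(values, index=[f"s{i}" for i in range(30)])
        r, p = stage_association(a, series)
        r_ref, p_ref = sps.pearsonr(stages, values)
        assert r == pytest.approx(r_ref) and p == pytest.approx(p_ref)

    def test_positive_age_slope_detected_in_late_like_cohort(self):
        from tdpstage.synthetic import preset, generate_cohort

        cfg = preset("LATE-like", seed=8)
        _, meta, truth = generate_cohort(cfg)
        n = cfg.n_subjects
        a = _assignments(truth["stage"].to_numpy())
        ages = pd.Series(meta["age_at_death"].to_numpy(),
                         index=[f"s{i}" for i in range(n)])
        r, p = stage_association(a, ages)
        assert r > 0.2 and p < 0.01

    def test_noiseless_total_pathology_rank_correlation_is_one(self, staged_cohort):
        from tdpstage.io import total_pathology_all

        _, table, _, truth = staged_cohort
        a = _assignments(truth["stage"].to_numpy())
        total = pd.Series(total_pathology_all(table).to_numpy(),
                          index=[f"s{i}" for i in range(table.n_subjects)])
        rho, _ = stage_association(a, total, method="spearman")
        assert rho == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        a = _assignments([2, 2, 2, 2])
        values = pd.Series([1, 2, 3, 4.0], index=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError):
            stage_association(a, values)

    def test_too_few_pairs_rejected(self):
        a = _assignments([0, 1])
        values = pd.Series([1, 2.0], index=["s0", "s1"])
        with pytest.raises(ValueError):
            stage_association(a, values)


class TestUnclassifiableTest:
    def _series(self, stages, probs):
        idx = [f"s{i}" for i in range(len(stages))]
        return pd.Series(stages, index=idx), pd.Series(probs, index=idx)

    def test_identical_groups_give_zero_t(self):
        stages, probs = self._series(
            ["I", "I", UNCLASSIFIABLE, UNCLASSIFIABLE],
            [0.5, 0.7, 0.5, 0.7],
        )
        t, _ = classifiable_vs_unclassifiable_test(stages, probs)
        assert t == pytest.approx(0.0)

    def test_direction_positive_when_classifiable_fit_better(self):
        stages, probs = self._series(
            ["I"] * 3 + [UNCLASSIFIABLE] * 3,
            [0.9, 0.9, 0.9, 0.1, 0.1, 0.1],
        )
        t, p = classifiable_vs_unclassifiable_test(stages, probs)
        assert t > 10

    def test_matches_welch_formula(self):
        a = np.array([0.9, 0.8, 0.85, 0.95])
        b = np.array([0.5, 0.6, 0.4])
        stages, probs = self._series(
            ["I"] * 4 + [UNCLASSIFIABLE] * 3, np.concatenate([a, b])
        )
        t, p = classifiable_vs_unclassifiable_test(stages, probs)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(float(t_ref))
        assert p == pytest.approx(float(p_ref))

    def test_tiny_group_rejected(self):
        stages, probs = self._series(["I", UNCLASSIFIABLE], [0.9, 0.1])
        with pytest.raises(ValueError):
            classifiable_vs_unclassifiable_test(stages, probs)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_never_below_p(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(25))
        q = benjamini_hochberg(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


def _cohort_with_subtype_effect(n=200, effect=0.0, n_regions=8, seed=0):
    """Two balanced subtypes, shared stage gradient, optional region-0 shift."""
    rng = np.random.default_rng(seed)
    stages = rng.integers(0, 15, n)
    subtype = rng.integers(0, 2, n)
    base = np.clip(stages[:, None] / 5.0 + rng.normal(0, 0.5, (n, n_regions)), 0, 3)
    base[:, 0] += effect * (subtype == 0)
    legal = np.array([0, 0.5, 1, 2, 3])
    snapped = legal[np.abs(base[:, :, None] - legal).argmin(axis=2)]
    table = RegionalScoreTable(
        pd.DataFrame(snapped, columns=[f"r{i}" for i in range(n_regions)],
                     index=[f"s{i}" for i in range(n)])
    )
    return table, _assignments(stages, subtype)


class TestRegionwiseGLM:
    def test_planted_effect_detected_with_correct_sign(self):
        table, assignments = _cohort_with_subtype_effect(effect=1.0, seed=2)
        res = regionwise_subtype_glm(table, assignments)
        assert res.loc["r0", "q"] < 0.05
        assert res.loc["r0", "t"] > 0  # more severe in subtype 1 (index 0)

    def test_antisymmetric_under_subtype_relabelling(self):
        table, assignments = _cohort_with_subtype_effect(effect=1.0, seed=3)
        res = regionwise_subtype_glm(table, assignments)
        flipped = [
            SubjectAssignment(a.subject_id, 1 - a.subtype, a.ml_stage,
                              a.stage_posterior, a.subtype_posterior,
                              a.fit_probability)
            for a in assignments
        ]
        res_flipped = regionwise_subtype_glm(table, flipped)
        np.testing.assert_allclose(res["t"], -res_flipped["t"], atol=1e-9)

    def test_null_any_discovery_rate_controlled(self):
        """Without a subtype effect, BH keeps the replicate-level
        any-discovery rate near the nominal 5% level."""
        hits = 0
        n_reps = 60
        for rep in range(n_reps):
            table, assignments = _cohort_with_subtype_effect(
                n=100, effect=0.0, seed=1000 + rep
            )
            res = regionwise_subtype_glm(table, assignments)
            hits += bool((res["q"] < 0.05).any())
        assert hits / n_reps <= 0.12  # small-sample slack around 0.05

    def test_single_subtype_rejected(self):
        table, assignments = _cohort_with_subtype_effect(effect=0.0, seed=4)
        mono = [
            SubjectAssignment(a.subject_id, 0, a.ml_stage, a.stage_posterior,
                              a.subtype_posterior, a.fit_probability)
            for a in assignments
        ]
        with pytest.raises(ValueError):
            regionwise_subtype_glm(table, mono)
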