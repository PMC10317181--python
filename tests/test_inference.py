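import numpy as np
import pytest

from tdpstage.inference import (
    FitConfig,
    _greedy_ascent,
    _objective,
    cross_validate_cvic,
    fit_single_sequence,
    fit_subtypes,
    mcmc_sample_sequences,
    stage_stratified_folds,
)
from tdpstage.progression import (
    _levels_ordered,
    build_event_set,
    enumerate_valid_sequences,
    log_probability_tensor,
    random_valid_sequence,
)
from tdpstage.score_model import ScoreProbabilityTensor, ratings_to_probabilities
from tdpstage.synthetic import (
    GeneratorConfig,
    generate_cohort,
    staircase_sequence,
    two_subtype_config,
)


def _random_probs(S, R, levels, seed):
    rng = np.random.default_rng(seed)
    p = np.zeros((S, R, 4))
    p[:, :, : levels + 1] = rng.dirichlet(np.ones(levels + 1), size=(S, R))
    return ScoreProbabilityTensor(
        p, [f"s{i}" for i in range(S)], [f"r{i}" for i in range(R)]
    )


class TestFitSingleSequence:
    def test_recovers_noiseless_staged_cohort(self, staged_cohort):
        cfg, table, _, _ = staged_cohort
        probs = ratings_to_probabilities(table)
        es = cfg.event_set
        fitted, _ = fit_single_sequence(
            probs, es, FitConfig(n_starts=3, seed=0)
        )
        assert np.array_equal(fitted.order, cfg.sequences[0].order)

    def test_single_region_forced_order(self):
        probs = _random_probs(5, 1, 3, seed=2)
        es = build_event_set(["r0"], 3)
        fitted, _ = fit_single_sequence(probs, es, FitConfig(n_starts=1, seed=0))
        assert fitted.tokens() == ["r0:1", "r0:2", "r0:3"]

    def test_greedy_never_decreases_objective(self):
        probs = _random_probs(10, 3, 2, seed=3)
        logp = log_probability_tensor(probs)
        es = build_event_set(probs.region_names, 2)
        rng = np.random.default_rng(0)
        start = random_valid_sequence(es, rng).order
        ll_start = _objective(logp, start)
        order, ll_end = _greedy_ascent(logp, start, 50)
        assert ll_end >= ll_start - 1e-12
        assert _levels_ordered(order, 3)

    def test_deterministic_given_seed(self):
        probs = _random_probs(15, 4, 2, seed=4)
        es = build_event_set(probs.region_names, 2)
        a, lla = fit_single_sequence(probs, es, FitConfig(n_starts=3, seed=9))
        b, llb = fit_single_sequence(probs, es, FitConfig(n_starts=3, seed=9))
        assert np.array_equal(a.order, b.order) and lla == llb

    def test_matches_enumeration_oracle_on_small_instances(self):
        """Greedy multi-start finds the global optimum on most M<=8 problems."""
        matches = 0
        n_trials = 30
        for trial in range(n_trials):
            R, L = (4, 2) if trial % 2 else (2, 3)
            probs = _random_probs(10, R, L, seed=100 + trial)
            es = build_event_set(probs.region_names, L)
            logp = log_probability_tensor(probs)
            _, ll = fit_single_sequence(
                probs, es, FitConfig(n_starts=8, seed=trial)
            )
            oracle = max(
                _objective(logp, s.order)
                for s in enumerate_valid_sequences(es)
            )
            matches += np.isclose(ll, oracle, atol=1e-9)
        assert matches >= 0.9 * n_trials


class TestMCMC:
    def _setup(self, seed=0):
        regions = tuple(f"R{i}" for i in range(5))
        es = build_event_set(regions, 2)
        seq = staircase_sequence(es, regions)
        cfg = GeneratorConfig(
            region_names=regions,
            sequences=[seq],
            fractions=(1.0,),
            n_subjects=6 * (es.n_events + 1),
            stage_distribution="uniform",
            noise_epsilon=0.0,
            seed=seed,
        )
        table, _, _ = generate_cohort(cfg)
        return es, seq, ratings_to_probabilities(table)

    def test_positional_density_rows_sum_to_one(self):
        es, seq, probs = self._setup()
        samples, density = mcmc_sample_sequences(
            probs, seq, FitConfig(mcmc_iterations=300, seed=1)
        )
        np.testing.assert_allclose(density.sum(axis=1), 1.0)
        assert (density >= 0).all()

    def test_all_samples_valid(self):
        es, seq, probs = self._setup()
        samples, _ = mcmc_sample_sequences(
            probs, seq, FitConfig(mcmc_iterations=300, seed=2)
        )
        assert samples
        for s in samples:
            assert _levels_ordered(s.order, es.n_regions)

    def test_noiseless_cohort_modal_positions_match_truth(self):
        es, seq, probs = self._setup(seed=3)
        _, density = mcmc_sample_sequences(
            probs, seq, FitConfig(mcmc_iterations=2000, seed=3)
        )
        L = es.max_score
        for pos, (r, s) in enumerate(seq.order):
            assert density[r * L + (s - 1)].argmax() == pos


class TestFitSubtypes:
    def test_c1_delegates_to_single_sequence(self):
        probs = _random_probs(12, 3, 2, seed=5)
        es = build_event_set(probs.region_names, 2)
        cfg = FitConfig(n_starts=3, mcmc_iterations=200, seed=7)
        model = fit_subtypes(probs, es, 1, cfg, run_mcmc=False)
        seq, ll = fit_single_sequence(probs, es, cfg)
        assert np.array_equal(model.sequences[0].order, seq.order)
        assert model.fractions.tolist() == [1.0]

    def test_two_reversed_subtypes_recovered(self):
        cfg = two_subtype_config(
            n_subjects=200, noise_epsilon=0.1, seed=7,
            stage_distribution="uniform",
        )
        table, _, truth = generate_cohort(cfg)
        probs = ratings_to_probabilities(table)
        model = fit_subtypes(
            probs, cfg.event_set, 2,
            FitConfig(n_starts=3, n_split_starts=2, mcmc_iterations=300,
                      seed=0),
        )
        assert model.fractions.sum() == pytest.approx(1.0)
        from tdpstage.assignment import assign_subtype_and_stage

        pred = np.array(
            [a.subtype for a in assign_subtype_and_stage(probs, model)]
        )
        true = truth["subtype"].to_numpy()
        acc = max((pred == true).mean(), (pred != true).mean())
        assert acc >= 0.9


class TestCrossValidation:
    def test_folds_partition_subjects_exactly_once(self):
        rng = np.random.default_rng(0)
        stages = rng.integers(0, 20, size=53)
        folds = stage_stratified_folds(stages, 10, rng)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(53))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            stage_stratified_folds(np.arange(5), 6, np.random.default_rng(0))

    def test_cvic_prefers_two_subtypes_when_planted(self):
        cfg = two_subtype_config(
            region_names=[f"R{i}" for i in range(5)],
            n_subjects=120, noise_epsilon=0.05, seed=3,
            stage_distribution="uniform",
        )
        table, _, _ = generate_cohort(cfg)
        probs = ratings_to_probabilities(table)
        res = cross_validate_cvic(
            probs, cfg.event_set, 2,
            FitConfig(n_starts=2, n_split_starts=2, mcmc_iterations=300,
                      max_stored_samples=50, n_folds=5, seed=0),
            np.random.default_rng(0),
        )
        assert res.selected == 2
        assert res.cvic[1] < res.cvic[0]
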