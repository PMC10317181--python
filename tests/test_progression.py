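import numpy as np
import pytest

from tdpstage.progression import (
    EventSequence,
    SequenceError,
    SubtypeModel,
    build_event_set,
    dataset_log_likelihood,
    enumerate_valid_sequences,
    log_probability_tensor,
    random_valid_sequence,
    stage_conditional_likelihood,
    stage_log_likelihood_matrix,
    subject_marginal_likelihood,
)
from tdpstage.score_model import ScoreProbabilityTensor


def _tensor(slices):
    """Build a tensor from a list of per-region 4-vectors (one subject)."""
    p = np.array([slices])
    return ScoreProbabilityTensor(
        p, ["s1"], [f"r{i}" for i in range(p.shape[1])]
    )


class TestEventSet:
    @pytest.mark.parametrize(
        "n_regions,levels,expected", [(20, 3, 60), (18, 3, 54), (19, 3, 57), (1, 1, 1)]
    )
    def test_event_count_is_regions_times_levels(self, n_regions, levels, expected):
        es = build_event_set([f"r{i}" for i in range(n_regions)], levels)
        assert es.n_events == expected

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            build_event_set([], 3)

    def test_each_region_level_pair_once(self):
        es = build_event_set(["a", "b"], 3)
        assert len({tuple(e) for e in es.events}) == 6


class TestEventSequence:
    def test_level_order_violation_rejected(self):
        es = build_event_set(["a"], 2)
        with pytest.raises(SequenceError):
            EventSequence(es, np.array([[0, 2], [0, 1]]))

    def test_token_round_trip(self):
        es = build_event_set(["a", "b"], 2)
        seq = random_valid_sequence(es, np.random.default_rng(0))
        back = EventSequence.from_tokens(es, seq.tokens())
        assert back == seq

    def test_implied_levels_monotone(self):
        es = build_event_set(["a", "b"], 3)
        seq = random_valid_sequence(es, np.random.default_rng(1))
        levels = seq.implied_levels()
        assert (np.diff(levels, axis=0) >= 0).all()
        assert levels[0].sum() == 0
        assert (levels[-1] == 3).all()


class TestLikelihood:
    def test_stage_conditional_hand_example(self, two_region_probs):
        es = build_event_set(["r1", "r2"], 1)
        seq = EventSequence(es, np.array([[0, 1], [1, 1]]))
        values = [
            stage_conditional_likelihood(two_region_probs, seq, "s1", k)
            for k in range(3)
        ]
        np.testing.assert_allclose(values, [0.14, 0.56, 0.24], atol=1e-12)

    def test_stage_zero_on_certain_baseline_is_one(self):
        probs = _tensor([[1.0, 0, 0, 0], [1.0, 0, 0, 0]])
        es = build_event_set(["r0", "r1"], 1)
        seq = EventSequence(es, np.array([[0, 1], [1, 1]]))
        assert stage_conditional_likelihood(probs, seq, "s1", 0) == pytest.approx(1.0)

    def test_single_event_likelihoods(self):
        probs = _tensor([[0.9, 0.1, 0, 0]])
        es = build_event_set(["r0"], 1)
        seq = EventSequence(es, np.array([[0, 1]]))
        assert stage_conditional_likelihood(probs, seq, "s1", 0) == pytest.approx(0.9)
        assert stage_conditional_likelihood(probs, seq, "s1", 1) == pytest.approx(0.1)
        assert subject_marginal_likelihood(probs, seq, "s1") == pytest.approx(0.5)

    def test_marginal_hand_example(self, two_region_probs):
        es = build_event_set(["r1", "r2"], 1)
        seq = EventSequence(es, np.array([[0, 1], [1, 1]]))
        assert subject_marginal_likelihood(
            two_region_probs, seq, "s1"
        ) == pytest.approx((0.14 + 0.56 + 0.24) / 3)

    def test_concentrated_prior_reduces_to_conditional(self, two_region_probs):
        es = build_event_set(["r1", "r2"], 1)
        seq = EventSequence(es, np.array([[0, 1], [1, 1]]))
        prior = np.array([0.0, 1.0, 0.0])
        assert subject_marginal_likelihood(
            two_region_probs, seq, "s1", prior
        ) == pytest.approx(0.56)

    def test_unnormalised_prior_rejected(self, two_region_probs):
        es = build_event_set(["r1", "r2"], 1)
        seq = EventSequence(es, np.array([[0, 1], [1, 1]]))
        with pytest.raises(ValueError):
            subject_marginal_likelihood(
                two_region_probs, seq, "s1", np.array([0.5, 0.5, 0.5])
            )

    def test_region_input_order_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(4), size=(4, 3))
        probs = ScoreProbabilityTensor(p, list("wxyz"), ["a", "b", "c"])
        perm = [2, 0, 1]
        probs_perm = ScoreProbabilityTensor(
            p[:, perm], list("wxyz"), ["c", "a", "b"]
        )
        es = build_event_set(["a", "b", "c"], 2)
        es_perm = build_event_set(["c", "a", "b"], 2)
        seq = random_valid_sequence(es, np.random.default_rng(0))
        name_map = {"a": 1, "b": 2, "c": 0}  # region index in permuted set
        seq_perm = EventSequence(
            es_perm,
            np.array([[name_map[es.region_names[r]], s] for r, s in seq.order]),
        )
        for subject in "wxyz":
            assert subject_marginal_likelihood(
                probs, seq, subject
            ) == pytest.approx(
                subject_marginal_likelihood(probs_perm, seq_perm, subject)
            )

    def test_stage_posterior_normalises(self, two_region_probs):
        es = build_event_set(["r1", "r2"], 1)
        seq = EventSequence(es, np.array([[0, 1], [1, 1]]))
        logp = log_probability_tensor(two_region_probs)
        mat = stage_log_likelihood_matrix(logp, seq)
        post = np.exp(mat) / np.exp(mat).sum(axis=1, keepdims=True)
        assert post.sum() == pytest.approx(1.0)


class TestDatasetLikelihood:
    def _probs(self, n_subjects, seed=0):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(4), size=(n_subjects, 2))
        return ScoreProbabilityTensor(
            p, [f"s{i}" for i in range(n_subjects)], ["a", "b"]
        )

    def test_single_subtype_reduces_to_sum_of_marginals(self):
        probs = self._probs(3)
        es = build_event_set(["a", "b"], 2)
        seq = random_valid_sequence(es, np.random.default_rng(1))
        model = SubtypeModel(es, [seq], np.array([1.0]))
        expected = sum(
            np.log(subject_marginal_likelihood(probs, seq, s))
            for s in probs.subject_ids
        )
        assert dataset_log_likelihood(probs, model) == pytest.approx(expected)

    def test_duplicating_subjects_doubles_loglik(self):
        probs = self._probs(3)
        doubled = ScoreProbabilityTensor(
            np.concatenate([probs.probs, probs.probs]),
            [f"s{i}" for i in range(6)],
            ["a", "b"],
        )
        es = build_event_set(["a", "b"], 2)
        seq = random_valid_sequence(es, np.random.default_rng(1))
        model = SubtypeModel(es, [seq], np.array([1.0]))
        assert dataset_log_likelihood(doubled, model) == pytest.approx(
            2 * dataset_log_likelihood(probs, model)
        )

    def test_two_subject_mixture_hand_computation(self):
        p = np.zeros((2, 1, 4))
        p[0, 0] = [0.9, 0.1, 0, 0]
        p[1, 0] = [0.2, 0.8, 0, 0]
        probs = ScoreProbabilityTensor(p, ["s1", "s2"], ["a"])
        es = build_event_set(["a"], 1)
        seq = EventSequence(es, np.array([[0, 1]]))
        model = SubtypeModel(es, [seq, seq], np.array([0.6, 0.4]))
        # marginal under seq is 0.5 for both; mixture = 0.6*0.5 + 0.4*0.5
        assert dataset_log_likelihood(probs, model) == pytest.approx(
            2 * np.log(0.5)
        )


class TestEnumeration:
    @pytest.mark.parametrize(
        "regions,levels,count",
        [(2, 1, 2), (1, 3, 1), (2, 2, 6), (3, 1, 6), (2, 3, 20)],
    )
    def test_counts_match_lattice_words(self, regions, levels, count):
        es = build_event_set([f"r{i}" for i in range(regions)], levels)
        assert len(enumerate_valid_sequences(es)) == count

    def test_all_enumerated_sequences_valid_and_unique(self):
        es = build_event_set(["a", "b"], 2)
        seqs = enumerate_valid_sequences(es)
        assert len({s.order.tobytes() for s in seqs}) == len(seqs)

    def test_guard_against_explosion(self):
        es = build_event_set([f"r{i}" for i in range(4)], 3)
        with pytest.raises(ValueError):
            enumerate_valid_sequences(es)
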