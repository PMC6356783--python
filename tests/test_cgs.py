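"""Collapsed Gibbs sampler: conditionals, sweeps, estimates, training."""

import numpy as np
import pytest

from dmrllda import (
    FeatureWeights,
    TrainConfig,
    estimate_parameters,
    gibbs_sweep,
    init_state,
    simulate,
    topic_conditional,
    train_cgs,
)
from conftest import collapsed_log_joint, enumerate_posterior


def _make_state(tokens, Lambda, alpha, lam, seed=0):
    rng = np.random.default_rng(seed)
    return init_state(
        [np.asarray(t, dtype=np.int64) for t in tokens],
        np.asarray(Lambda),
        np.asarray(alpha, dtype=float),
        np.asarray(lam, dtype=float),
        rng,
    )


class TestInitState:
    def test_counts_consistent_after_init(self):
        state = _make_state(
            [[0, 1, 2], [2, 3]], [[1, 1, 0], [0, 1, 1]],
            np.ones((2, 3)), np.ones(4),
        )
        state.audit()

    def test_single_label_doc_forced(self):
        state = _make_state([[0, 1, 1]], [[0, 1, 0]], np.ones((1, 3)), np.ones(2))
        assert (state.assignments == 1).all()

    def test_no_active_labels_rejected(self):
        with pytest.raises(ValueError, match="no active labels"):
            _make_state([[0]], [[0, 0]], np.ones((1, 2)), np.ones(1))

    def test_fixed_seed_reproduces_assignments(self):
        a = _make_state([[0, 1, 0, 1]], [[1, 1, 1]], np.ones((1, 3)), np.ones(2), seed=9)
        b = _make_state([[0, 1, 0, 1]], [[1, 1, 1]], np.ones((1, 3)), np.ones(2), seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)


class TestTopicConditional:
    def test_single_support_is_one_hot(self):
        state = _make_state([[0, 1]], [[0, 1, 0]], np.ones((1, 3)), np.ones(2))
        np.testing.assert_allclose(topic_conditional(state, 0, 0), [0, 1, 0])

    def test_symmetric_topics_split_evenly(self):
        # one token, two active topics, equal alpha: removing the token leaves
        # empty counts, so both topics are exchangeable
        state = _make_state([[0]], [[1, 1]], np.full((1, 2), 0.7), np.ones(3))
        np.testing.assert_allclose(topic_conditional(state, 0, 0), [0.5, 0.5])

    def test_counts_restored_after_evaluation(self):
        state = _make_state([[0, 1, 1]], [[1, 1]], np.ones((1, 2)), np.ones(2))
        before = (state.N_dt.copy(), state.N_tw.copy(), state.N_t.copy())
        topic_conditional(state, 0, 2)
        np.testing.assert_array_equal(before[0], state.N_dt)
        np.testing.assert_array_equal(before[1], state.N_tw)
        np.testing.assert_array_equal(before[2], state.N_t)

    def test_matches_collapsed_joint_ratio(self):
        """Oracle: conditional equals the ratio of collapsed joints summed
        over the removed token's topic, enumerated by brute force."""
        rng = np.random.default_rng(17)
        tokens = [rng.integers(0, 4, size=3), rng.integers(0, 4, size=2)]
        Lambda = np.array([[1, 1, 0], [1, 0, 1]])
        alpha = rng.uniform(0.3, 2.0, size=(2, 3))
        lam = rng.uniform(0.2, 1.5, size=4)
        state = _make_state(tokens, Lambda, alpha, lam, seed=3)
        for d in range(2):
            sl = slice(state.doc_offsets[d], state.doc_offsets[d + 1])
            for n in range(tokens[d].size):
                got = topic_conditional(state, d, n)
                logps = np.full(3, -np.inf)
                for t in np.nonzero(Lambda[d])[0]:
                    assign = [state.assignments[
                        state.doc_offsets[dd] : state.doc_offsets[dd + 1]
                    ].copy() for dd in range(2)]
                    assign[d][n] = t
                    logps[t] = collapsed_log_joint(assign, tokens, Lambda, alpha, lam)
                finite = np.isfinite(logps)
                expected = np.zeros(3)
                expected[finite] = np.exp(logps[finite] - logps[finite].max())
                expected /= expected.sum()
                np.testing.assert_allclose(got, expected, atol=1e-10)


class TestGibbsSweep:
    def test_count_audit_after_sweeps(self):
        state = _make_state(
            [[0, 1, 2, 0], [3, 3, 1]], [[1, 1, 0], [1, 0, 1]],
            np.ones((2, 3)), np.full(4, 0.5),
        )
        for _ in range(5):
            gibbs_sweep(state)
        state.audit()

    def test_single_label_corpus_sweep_is_noop(self):
        state = _make_state(
            [[0, 1], [1, 0]], [[1, 0], [0, 1]], np.ones((2, 2)), np.ones(2)
        )
        before = state.assignments.copy()
        gibbs_sweep(state)
        np.testing.assert_array_equal(state.assignments, before)

    def test_label_mask_never_violated(self):
        corpus, _ = simulate(T=4, W=10, F=1, D=15, Nd=12, seed=5)
        rng = np.random.default_rng(0)
        state = init_state(
            corpus, corpus.labels.matrix, np.ones((15, 4)), np.full(10, 0.3), rng
        )
        for _ in range(10):
            gibbs_sweep(state)
        assert (state.N_dt[corpus.labels.matrix == 0] == 0).all()

    def test_long_run_frequencies_match_enumerated_posterior(self):
        """2-token chain vs. the exact collapsed posterior (enumeration)."""
        tokens = [np.array([0, 1])]
        Lambda = np.array([[1, 1]])
        alpha = np.array([[0.9, 1.4]])
        lam = np.array([0.6, 1.1, 0.8])
        exact = enumerate_posterior(tokens, Lambda, alpha, lam)
        state = _make_state(tokens, Lambda, alpha, lam, seed=8)
        n_sweeps, burn = 12_000, 500
        counts = {s: 0 for s in exact}
        trace = []
        for sweep in range(n_sweeps + burn):
            gibbs_sweep(state)
            if sweep >= burn:
                s = tuple(state.assignments)
                counts[s] += 1
                trace.append(s)
        for s, p in exact.items():
            freq = counts[s] / n_sweeps
            # batch-means Monte-Carlo standard error (chain is autocorrelated)
            ind = np.array([t == s for t in trace], dtype=float)
            batches = ind[: (n_sweeps // 100) * 100].reshape(-1, 100).mean(axis=1)
            se = batches.std(ddof=1) / np.sqrt(batches.size)
            assert abs(freq - p) < 3 * max(se, 1e-4), (s, freq, p, se)


class TestEstimateParameters:
    def test_prior_only_gives_uniform_theta(self):
        alpha = np.ones((1, 2))
        Lambda = np.ones((1, 2))
        lam = np.ones(3)
        pi, theta = estimate_parameters(
            alpha, Lambda, lam, [np.zeros((1, 2))], [np.zeros((2, 3))]
        )
        np.testing.assert_allclose(theta, 1.0 / 3)

    def test_hand_arithmetic(self):
        # W=2, lam=1 symmetric, E[Ntw] = [3, 1] -> theta = [4/6, 2/6]
        alpha = np.ones((1, 1))
        lam = np.ones(2)
        _, theta = estimate_parameters(
            alpha, np.ones((1, 1)), lam, [np.array([[4.0]])], [np.array([[3.0, 1.0]])]
        )
        np.testing.assert_allclose(theta, [[4 / 6, 2 / 6]])

    def test_pi_rows_sum_to_one_over_active_labels(self):
        alpha = np.array([[0.5, 2.0, 1.0]])
        Lambda = np.array([[1.0, 0.0, 1.0]])
        pi, _ = estimate_parameters(
            alpha, Lambda, np.ones(2), [np.array([[3.0, 0.0, 1.0]])],
            [np.zeros((3, 2))],
        )
        np.testing.assert_allclose(pi.sum(axis=1), 1.0)
        assert pi[0, 1] == 0.0

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            estimate_parameters(np.ones((1, 1)), np.ones((1, 1)), np.ones(1), [], [])


class TestTrainCGS:
    def test_default_schedule_records_twenty_states(self):
        corpus, _ = simulate(T=3, W=10, F=1, D=5, Nd=10, seed=21)
        model = train_cgs(corpus, TrainConfig(seed=1))  # stock schedule
        assert model.config["n_recorded"] == 20

    def test_feature_frozen_reduction_keeps_initial_weights(self):
        corpus, _ = simulate(T=3, W=10, F=2, D=10, Nd=15, seed=22)
        cfg = TrainConfig(iterations=150, burn_in=50, thin=10, records=10,
                          update_features=False, seed=2)
        model = train_cgs(corpus, cfg)
        expected = FeatureWeights.initial(3, 2, alpha_init=50.0 / 3).matrix
        np.testing.assert_array_equal(model.beta_hat.matrix, expected)

    def test_theta_rows_are_distributions(self, small_corpus, quick_train_config):
        corpus, _ = small_corpus
        model = train_cgs(corpus, quick_train_config)
        np.testing.assert_allclose(model.theta_hat.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(model.pi_hat_train.sum(axis=1), 1.0, atol=1e-12)

    def test_training_is_seed_deterministic(self):
        corpus, _ = simulate(T=3, W=10, F=1, D=8, Nd=10, seed=23)
        cfg = TrainConfig(iterations=100, burn_in=40, thin=10, records=6, seed=5)
        m1 = train_cgs(corpus, cfg)
        m2 = train_cgs(corpus, cfg)
        np.testing.assert_array_equal(m1.theta_hat, m2.theta_hat)
        np.testing.assert_array_equal(m1.beta_hat.matrix, m2.beta_hat.matrix)
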