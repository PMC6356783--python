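"""Fold-in prediction, binarization, metrics, and cross-validation."""

import numpy as np
import pytest
from sklearn.metrics import f1_score

from dmrllda import (
    CVConfig,
    FeatureWeights,
    FittedModel,
    PredictConfig,
    TrainConfig,
    binarize,
    compute_metrics,
    cross_validate,
    predict,
    simulate,
    tune_threshold,
)
from dmrllda.generative import synthetic_vocabulary


def _uniform_model(T=3, W=6, F=1):
    return FittedModel(
        theta_hat=np.full((T, W), 1.0 / W),
        beta_hat=FeatureWeights(matrix=np.zeros((T, F + 1))),
        lam=np.full(W, 200.0 / W),
        vocabulary=synthetic_vocabulary(W),
        label_names=[f"L{t}" for t in range(T)],
        feature_names=[f"f{j}" for j in range(F)],
        transform=None,
        config={},
    )


class TestPredict:
    @pytest.mark.parametrize("method", ["cgs", "cvb0"])
    def test_uniform_model_gives_uniform_scores(self, method):
        model = _uniform_model()
        tokens = [np.array([0, 1, 2]), np.array([3, 4])]
        feats = np.zeros((2, 1))
        cfg = PredictConfig(method=method, iterations=2000, burn_in=500, thin=5,
                            seed=4)
        pred = predict(model, tokens, features=feats, config=cfg)
        np.testing.assert_allclose(pred.scores.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(pred.scores, 1.0 / 3, atol=0.05)

    def test_single_label_documents_recovered(self):
        """Docs generated from one label with well-separated topics score
        that label on top in >= 95% of seeded replicates."""
        rng = np.random.default_rng(33)
        T, W = 4, 20
        # well-separated: each topic concentrated on its own word block
        theta = np.full((T, W), 0.01 / (W - 5))
        for t in range(T):
            theta[t, t * 5 : (t + 1) * 5] = 0.99 / 5
        theta /= theta.sum(axis=1, keepdims=True)
        model = _uniform_model(T=T, W=W)
        model.theta_hat = theta
        hits = 0
        cfg = PredictConfig(method="cvb0", seed=0)
        for rep in range(100):
            label = rep % T
            tokens = [rng.choice(W, size=30, p=theta[label])]
            pred = predict(model, tokens, features=np.zeros((1, 1)), config=cfg)
            hits += int(np.argmax(pred.scores[0]) == label)
        assert hits >= 95

    def test_feature_raises_score_of_aligned_label(self):
        """Doubling a feature with large positive weight on label l raises
        l's predicted weight on otherwise identical documents."""
        model = _uniform_model(T=3, W=6, F=1)
        model.beta_hat = FeatureWeights(
            matrix=np.array([[2.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        )
        tokens = [np.array([0, 1]), np.array([0, 1])]
        feats = np.array([[1.0], [2.0]])
        pred = predict(model, tokens, features=feats,
                       config=PredictConfig(method="cvb0"))
        assert pred.scores[1, 0] > pred.scores[0, 0]

    def test_candidate_mask_respected(self):
        model = _uniform_model(T=3)
        mask = np.array([[1, 0, 1]])
        pred = predict(model, [np.array([0, 1])], features=np.zeros((1, 1)),
                       config=PredictConfig(method="cvb0"), candidate_mask=mask)
        assert pred.scores[0, 1] == 0.0
        np.testing.assert_allclose(pred.scores.sum(axis=1), 1.0)

    def test_feature_dimension_mismatch(self):
        model = _uniform_model(F=2)
        with pytest.raises(ValueError, match="features"):
            predict(model, [np.array([0])], features=np.zeros((1, 1)))


class TestBinarize:
    def test_one_hot_scores_give_single_labels(self):
        scores = np.eye(3)
        np.testing.assert_array_equal(binarize(scores), np.eye(3, dtype=int))

    def test_uniform_scores_turn_every_label_on(self):
        scores = np.full((2, 4), 0.25)
        assert binarize(scores).all()  # boundary >= 1/L

    def test_unknown_policy(self):
        with pytest.raises(ValueError, match="policy"):
            binarize(np.zeros((1, 2)), policy="magic")

    def test_tuned_threshold_matches_exhaustive_scan(self):
        """4-gene worked example: compare against a dense-grid scan."""
        scores = np.array(
            [[0.7, 0.2, 0.1], [0.4, 0.4, 0.2], [0.1, 0.6, 0.3], [0.3, 0.3, 0.4]]
        )
        truth = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1]])
        thr = tune_threshold(scores, truth)
        best_f1 = f1_score(truth, (scores >= thr).astype(int), average="micro")
        grid_best = max(
            f1_score(truth, (scores >= g).astype(int), average="micro",
                     zero_division=0)
            for g in np.linspace(0.0, 1.0, 2001)
        )
        assert best_f1 == pytest.approx(grid_best, abs=1e-12)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        truth = np.array([[1, 0, 1], [0, 1, 0]])
        scores = truth / truth.sum(axis=1, keepdims=True)
        rep = compute_metrics(scores, truth, truth)
        assert rep.hamming_loss == 0.0
        assert rep.average_precision == 1.0
        assert rep.one_error == 0.0
        assert rep.micro_f1 == rep.macro_f1 == 1.0
        assert rep.aupr_macro == rep.aupr_pooled == rep.aupr_weighted == 1.0

    def test_two_gene_three_label_hand_fixture(self):
        """All eight metrics against explicit hand computation."""
        scores = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]])
        truth = np.array([[1, 0, 1], [0, 1, 0]])
        pred = binarize(scores)  # uniform policy, cut at 1/3
        np.testing.assert_array_equal(pred, [[1, 0, 0], [0, 1, 0]])
        rep = compute_metrics(scores, pred, truth)
        assert rep.hamming_loss == pytest.approx(1 / 6)
        assert rep.average_precision == pytest.approx(11 / 12)
        assert rep.one_error == 0.0
        assert rep.micro_f1 == pytest.approx(0.8)
        assert rep.macro_f1 == pytest.approx(2 / 3)
        assert rep.aupr_macro == pytest.approx(5 / 6)
        assert rep.aupr_pooled == pytest.approx(5 / 6)
        assert rep.aupr_weighted == pytest.approx(5 / 6)

    def test_identical_per_label_curves_equalize_macro_and_weighted(self):
        scores = np.array([[0.9, 0.9], [0.1, 0.1]])
        truth = np.array([[1, 1], [0, 0]])
        rep = compute_metrics(scores, (scores > 0.5).astype(int), truth)
        assert rep.aupr_macro == rep.aupr_weighted

    def test_pooled_aupr_invariant_to_label_permutation(self):
        rng = np.random.default_rng(0)
        scores = rng.random((10, 4))
        truth = (rng.random((10, 4)) < 0.4).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        perm = [2, 0, 3, 1]
        r1 = compute_metrics(scores, binarize(scores), truth)
        r2 = compute_metrics(
            scores[:, perm], binarize(scores[:, perm]), truth[:, perm]
        )
        assert r1.aupr_pooled == pytest.approx(r2.aupr_pooled)

    def test_empty_truth_rows_excluded_with_count(self):
        scores = np.array([[0.9, 0.1], [0.5, 0.5]])
        truth = np.array([[1, 0], [0, 0]])
        rep = compute_metrics(scores, binarize(scores), truth)
        assert rep.n_excluded == 1
        assert rep.average_precision == 1.0

    def test_all_metrics_bounded(self):
        rng = np.random.default_rng(1)
        scores = rng.dirichlet(np.ones(5), size=12)
        truth = (rng.random((12, 5)) < 0.3).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        rep = compute_metrics(scores, binarize(scores), truth)
        for v in rep.to_dict().values():
            assert 0.0 <= v <= 1.0


@pytest.fixture(scope="module")
def cv_result():
    corpus, _ = simulate(T=3, W=12, F=2, D=25, Nd=20, seed=40)
    cfg = CVConfig(
        n_folds=5,
        n_rounds=2,
        seed=5,
        train=TrainConfig(iterations=80, burn_in=40, thin=10, records=4,
                          beta_interval=20, beta_burnin=30, seed=1),
        predict=PredictConfig(method="cvb0", seed=1),
    )
    return cross_validate(corpus, cfg), corpus, cfg


class TestCrossValidate:
    def test_partitions_cover_all_genes(self, cv_result):
        result, corpus, cfg = cv_result
        for fold_of in result.fold_assignments:
            assert fold_of.size == corpus.n_documents
            assert set(fold_of) == set(range(cfg.n_folds))
            # every gene in exactly one fold per round is structural
        assert len(result.folds) == cfg.n_folds * cfg.n_rounds

    def test_fixed_seed_reproduces_folds_and_metrics(self, cv_result):
        result, corpus, cfg = cv_result
        again = cross_validate(corpus, cfg)
        for a, b in zip(result.fold_assignments, again.fold_assignments):
            np.testing.assert_array_equal(a, b)
        assert result.mean.to_dict() == again.mean.to_dict()

    def test_metrics_bounded(self, cv_result):
        result, _, _ = cv_result
        for v in result.mean.to_dict().values():
            assert 0.0 <= v <= 1.0

    def test_too_few_genes_rejected(self):
        corpus, _ = simulate(T=2, W=8, F=1, D=3, Nd=5, seed=41)
        with pytest.raises(ValueError, match="genes"):
            cross_validate(corpus, CVConfig(n_folds=5, n_rounds=1))

    def test_bmd_wrapped_pipeline_runs(self):
        corpus, _ = simulate(T=4, W=10, F=1, D=15, Nd=15, seed=42)
        cfg = CVConfig(
            n_folds=3,
            n_rounds=1,
            seed=2,
            use_bmd=True,
            train=TrainConfig(iterations=60, burn_in=30, thin=10, records=3,
                              update_features=False, seed=1),
            predict=PredictConfig(method="cvb0", seed=1),
        )
        result = cross_validate(corpus, cfg)
        for v in result.mean.to_dict().values():
            assert 0.0 <= v <= 1.0
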