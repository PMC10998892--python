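"""Predictors: edge vectorization, anatomical prior, FCNET/Huber/null, LOO."""

import numpy as np
import pytest

from tumorconn.assembly import Connectome, log_transform
from tumorconn.evaluation import reconstruction_metrics
from tumorconn.predictor import (
    AnatomicalPrior,
    PredictorConfig,
    build_anatomical_prior,
    devectorize_edges,
    evaluate_prediction,
    fcnet_train,
    huber_benchmark,
    loo_cross_validate,
    null_benchmark,
    predict,
    vectorize_edges,
)


def connectome_from_vector(vec, n, log_scale=False, n_inactive=0):
    labels = tuple(f"n{i}" for i in range(n + n_inactive))
    mask = np.array([True] * n + [False] * n_inactive)
    template = Connectome(
        weights=np.zeros((n + n_inactive, n + n_inactive)),
        node_labels=labels,
        active_mask=mask,
        log_scale=log_scale,
    )
    return devectorize_edges(np.asarray(vec, float), template)


class TestVectorization:
    def test_atlas_dialect_yields_13695_edges(self):
        """170-label atlas with 4 empty labels -> 166 active -> 13695 edges."""
        c = connectome_from_vector(np.zeros(166 * 165 // 2), n=166, n_inactive=4)
        assert vectorize_edges(c).size == 13695

    def test_three_node_toy_ordering(self):
        c = connectome_from_vector([1.0, 2.0, 3.0], n=3)
        assert c.weights[0, 1] == 1.0 and c.weights[0, 2] == 2.0 and c.weights[1, 2] == 3.0
        np.testing.assert_array_equal(vectorize_edges(c), [1.0, 2.0, 3.0])

    def test_round_trip_identity(self, rng):
        vec = rng.uniform(0, 10, 6 * 5 // 2)
        c = connectome_from_vector(vec, n=6, n_inactive=2)
        np.testing.assert_array_equal(vectorize_edges(c), vec)

    def test_wrong_length_rejected(self):
        c = connectome_from_vector(np.zeros(10), n=5)
        with pytest.raises(ValueError):
            devectorize_edges(np.zeros(11), c)


class TestAnatomicalPrior:
    def make_pool(self, presence_per_edge, n=4):
        """presence_per_edge: list over edges of how many of 6 controls have it."""
        pool = []
        for k in range(6):
            vec = [10.0 if k < m else 0.0 for m in presence_per_edge]
            pool.append(connectome_from_vector(vec, n=n))
        return pool

    def test_presence_fractions_and_threshold(self):
        pool = self.make_pool([6, 0, 3, 4, 5, 2])
        prior = build_anatomical_prior(pool, tau=0.6)
        np.testing.assert_allclose(prior.edge_weights, [1.0, 0.0, 0.5, 2 / 3, 5 / 6, 1 / 3])
        np.testing.assert_array_equal(prior.support, [True, False, False, True, True, False])

    def test_ubiquitous_edge_survives_any_threshold(self):
        pool = self.make_pool([6, 6, 6, 0, 0, 0])
        prior = build_anatomical_prior(pool, tau=1.0)
        assert prior.support[:3].all() and not prior.support[3:].any()

    def test_log_scale_inputs_rejected(self):
        pool = [log_transform(c) for c in self.make_pool([6] * 6)]
        with pytest.raises(ValueError):
            build_anatomical_prior(pool)


def toy_training_setup(rng, n_nodes=12, n_subjects=8, post_from_pre=lambda x: x):
    n_edges = n_nodes * (n_nodes - 1) // 2
    template = rng.uniform(1.0, 4.0, n_edges)
    pairs = []
    for _ in range(n_subjects):
        pre = template + 0.1 * rng.standard_normal(n_edges)
        pairs.append((pre, post_from_pre(pre)))
    prior = AnatomicalPrior(edge_weights=np.ones(n_edges), threshold=0.0)
    return pairs, prior


class TestFcnet:
    def test_training_reduces_held_out_error_on_self_map(self, rng):
        pairs, prior = toy_training_setup(rng)
        cfg = PredictorConfig(seed=0, hidden_units=32)
        model = fcnet_train(pairs[:-1], prior, cfg)
        pre, post = pairs[-1]
        trained_mse = reconstruction_metrics(model.predict_vector(pre), post).mse
        untrained_mse = reconstruction_metrics(np.zeros_like(post), post).mse
        assert trained_mse < untrained_mse

    def test_excluded_edges_predict_exact_zero(self, rng):
        pairs, _ = toy_training_setup(rng)
        n_edges = pairs[0][0].size
        weights = rng.uniform(0, 1, n_edges)
        prior = AnatomicalPrior(edge_weights=weights, threshold=0.5)
        model = fcnet_train(pairs, prior, PredictorConfig(seed=1, hidden_units=16))
        pred = model.predict_vector(rng.uniform(0, 5, n_edges))
        assert np.all(pred[~prior.support] == 0.0)

    def test_same_seed_reproduces_training_curves(self, rng):
        pairs, prior = toy_training_setup(rng)
        cfg = PredictorConfig(seed=42, hidden_units=16)
        m1 = fcnet_train(pairs, prior, cfg)
        m2 = fcnet_train(pairs, prior, cfg)
        assert m1.training_curve == m2.training_curve
        assert m1.validation_curve == m2.validation_curve
        np.testing.assert_array_equal(m1.w1, m2.w1)

    def test_validation_recorded_at_requested_cadence(self, rng):
        pairs, prior = toy_training_setup(rng)
        cfg = PredictorConfig(seed=0, hidden_units=8, epochs=100, val_every=20)
        model = fcnet_train(pairs, prior, cfg)
        assert [e for e, _ in model.validation_curve] == [20, 40, 60, 80, 100]
        assert len(model.training_curve) == 100

    def test_too_few_pairs_rejected(self, rng):
        pairs, prior = toy_training_setup(rng, n_subjects=1)
        with pytest.raises(ValueError):
            fcnet_train(pairs, prior, PredictorConfig(seed=0))


class TestHuber:
    def test_exact_linear_recovery(self, rng):
        pairs, prior = toy_training_setup(rng, post_from_pre=lambda x: 2.0 * x)
        model = huber_benchmark(pairs, prior)
        assert model.slope == pytest.approx(2.0, abs=1e-6)
        assert model.intercept == pytest.approx(0.0, abs=1e-5)

    def test_robust_to_gross_outliers(self, rng):
        n_edges = 66
        template = rng.uniform(1.0, 4.0, n_edges)
        pairs = []
        for _ in range(10):
            pre = template + 0.05 * rng.standard_normal(n_edges)
            post = pre.copy()
            k = rng.integers(0, n_edges)  # 1-2% gross outliers
            post[k] += 50.0
            pairs.append((pre, post))
        prior = AnatomicalPrior(edge_weights=np.ones(n_edges), threshold=0.0)
        huber_slope = huber_benchmark(pairs, prior).slope
        xs = np.concatenate([p for p, _ in pairs])
        ys = np.concatenate([q for _, q in pairs])
        ols_slope = np.polyfit(xs, ys, 1)[0]
        assert abs(huber_slope - 1.0) < abs(ols_slope - 1.0)

    def test_prior_gating_zeroes_excluded_edges(self, rng):
        pairs, _ = toy_training_setup(rng)
        n_edges = pairs[0][0].size
        prior = AnatomicalPrior(edge_weights=(np.arange(n_edges) % 2).astype(float), threshold=0.5)
        model = huber_benchmark(pairs, prior)
        pred = model.predict_vector(rng.uniform(1, 5, n_edges))
        assert np.all(pred[~prior.support] == 0.0)


class TestNull:
    def test_same_seed_gives_identical_predictions(self, rng):
        prior = AnatomicalPrior(edge_weights=np.ones(45), threshold=0.0)
        x = rng.uniform(0, 5, 45)
        p1 = null_benchmark(prior, seed=9).predict_vector(x)
        p2 = null_benchmark(prior, seed=9).predict_vector(x)
        np.testing.assert_array_equal(p1, p2)

    def test_zero_input_maps_to_zero(self):
        prior = AnatomicalPrior(edge_weights=np.ones(45), threshold=0.0)
        np.testing.assert_array_equal(
            null_benchmark(prior, seed=0).predict_vector(np.zeros(45)), np.zeros(45)
        )

    def test_pcc_centred_near_zero_across_seeds(self, rng):
        n_edges = 300
        prior = AnatomicalPrior(edge_weights=np.ones(n_edges), threshold=0.0)
        x = rng.uniform(1, 5, n_edges)
        y = rng.uniform(1, 5, n_edges)
        pccs = [
            reconstruction_metrics(null_benchmark(prior, seed=s).predict_vector(x), y).pcc
            for s in range(50)
        ]
        assert abs(np.mean(pccs)) < 0.05

    def test_excluded_edges_zero(self, rng):
        prior = AnatomicalPrior(edge_weights=np.zeros(45), threshold=0.5)
        pred = null_benchmark(prior, seed=1).predict_vector(rng.uniform(0, 5, 45))
        np.testing.assert_array_equal(pred, np.zeros(45))


class TestPredictOp:
    def test_negative_log_outputs_filtered_in_native_matrix(self, rng):
        n = 5
        n_edges = n * (n - 1) // 2
        prior = AnatomicalPrior(edge_weights=np.ones(n_edges), threshold=0.0)
        model = null_benchmark(prior, seed=3)
        pre = log_transform(connectome_from_vector(rng.uniform(1, 50, n_edges), n=n))
        result = predict(model, pre, output_filter_native_weight=1.0)
        native = vectorize_edges(result.connectome)
        raw_native = np.expm1(result.raw_vector)
        assert np.all(native[raw_native < 1.0] == 0.0)
        np.testing.assert_allclose(native[raw_native >= 1.0], raw_native[raw_native >= 1.0])

    def test_output_is_symmetric_with_zero_diagonal(self, rng):
        n = 6
        n_edges = n * (n - 1) // 2
        prior = AnatomicalPrior(edge_weights=np.ones(n_edges), threshold=0.0)
        model = null_benchmark(prior, seed=4)
        pre = log_transform(connectome_from_vector(rng.uniform(1, 50, n_edges), n=n))
        out = predict(model, pre).connectome
        np.testing.assert_array_equal(out.weights, out.weights.T)
        assert np.all(np.diag(out.weights) == 0)

    def test_native_scale_input_rejected(self, rng):
        n_edges = 10
        prior = AnatomicalPrior(edge_weights=np.ones(n_edges), threshold=0.0)
        pre = connectome_from_vector(rng.uniform(1, 50, n_edges), n=5)
        with pytest.raises(ValueError):
            predict(null_benchmark(prior, seed=0), pre)


class TestLooCrossValidation:
    def make_cohort(self, rng, n_subjects):
        pairs, prior = toy_training_setup(rng, n_subjects=n_subjects)
        cohort = [(f"sub{i}", pre, post) for i, (pre, post) in enumerate(pairs)]
        return cohort, prior

    def test_one_fold_per_subject(self, rng):
        cohort, prior = self.make_cohort(rng, 5)
        folds = loo_cross_validate(cohort, prior, PredictorConfig(seed=0, hidden_units=8))
        assert [f.left_out_id for f in folds] == [c[0] for c in cohort]

    def test_cohort_of_three_trains_on_two(self, rng):
        cohort, prior = self.make_cohort(rng, 3)
        folds = loo_cross_validate(cohort, prior, PredictorConfig(seed=0, hidden_units=8))
        assert len(folds) == 3

    def test_fold_metrics_equal_standalone_evaluation(self, rng):
        cohort, prior = self.make_cohort(rng, 4)
        folds = loo_cross_validate(cohort, prior, PredictorConfig(seed=0, hidden_units=8))
        for fold, (_, _, post) in zip(folds, cohort):
            again = evaluate_prediction(fold.pred_vector, post)
            assert fold.metrics == again

    def test_repeated_runs_identical(self, rng):
        cohort, prior = self.make_cohort(rng, 4)
        cfg = PredictorConfig(seed=7, hidden_units=8)
        f1 = loo_cross_validate(cohort, prior, cfg)
        f2 = loo_cross_validate(cohort, prior, cfg)
        for a, b in zip(f1, f2):
            assert a.metrics == b.metrics
            np.testing.assert_array_equal(a.pred_vector, b.pred_vector)

    def test_small_cohort_rejected(self, rng):
        cohort, prior = self.make_cohort(rng, 2)
        with pytest.raises(ValueError):
            loo_cross_validate(cohort, prior, PredictorConfig(seed=0))

    def test_unknown_model_kind_rejected(self, rng):
        cohort, prior = self.make_cohort(rng, 3)
        with pytest.raises(ValueError):
            loo_cross_validate(cohort, prior, PredictorConfig(seed=0), model_kind="svm")
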