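"""Hybrid 1D-CNN/GRU classifier: equations oracle, training, metrics, search."""

import numpy as np
import pandas as pd
import pytest

from gcgrader.errors import EvaluationError, ParameterError, TrainingError
from gcgrader.net import (
    HybridNet,
    MetricsReport,
    ModelBundle,
    ModelConfig,
    SearchSpace,
    compute_metrics,
    evaluate,
    hyperparameter_search,
    reference_forward,
    saliency,
    train,
)
from gcgrader.net.engine import sigmoid


class TestArchitecture:
    def test_intermediate_shapes_for_44_gene_signature(self):
        net = HybridNet(ModelConfig(), 44)
        assert net.shapes["conv"] == (43, 64)   # 44 - 2 + 1
        assert net.shapes["pool"] == (21, 64)   # floor(43 / 2)
        assert net.shapes["gru"] == (64,)
        assert net.shapes["dense"] == (192,)
        assert net.shapes["output"] == (2,)

    def test_output_in_unit_interval(self):
        net = HybridNet(ModelConfig(), 30)
        X = np.random.default_rng(0).random((8, 30))
        p = net.forward(X)
        assert (p >= 0).all() and (p <= 1).all()

    def test_defaults_match_published_architecture(self):
        cfg = ModelConfig()
        assert (cfg.conv_filters, cfg.kernel_size, cfg.pool_size) == (64, 2, 2)
        assert (cfg.gru_units, cfg.dense_units, cfg.n_classes) == (64, 192, 2)
        assert cfg.conv_dropout == cfg.gru_dropout == cfg.dense_dropout == 0.2
        assert (cfg.learning_rate, cfg.epochs, cfg.batch_size, cfg.seed) == (
            0.001, 10, 32, 42,
        )

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ParameterError):
            HybridNet(ModelConfig(kernel_size=10), 5)

    def test_normalized_probabilities_sum_to_one(self):
        net = HybridNet(ModelConfig(), 25)
        X = np.random.default_rng(1).random((12, 25))
        p = net.predict_proba(X)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestReferenceForward:
    def test_zero_weights_give_half_half(self):
        net = HybridNet(ModelConfig(conv_filters=4, gru_units=3, dense_units=5), 9)
        weights = {k: np.zeros_like(v) for k, v in net.state_dict().items()}
        weights["bn_moving_var"] = np.ones_like(weights["bn_moving_var"])
        out = reference_forward(weights, net.config, np.random.default_rng(0).random(9))
        assert np.allclose(out, [0.5, 0.5])

    def test_agrees_with_engine_on_random_draws(self):
        """Ten random weight/input draws: the scalar-loop equations match
        the vectorized engine to far better than 1e-4."""
        rng = np.random.default_rng(7)
        for trial in range(10):
            cfg = ModelConfig(
                conv_filters=int(rng.integers(2, 8)),
                gru_units=int(rng.integers(2, 8)),
                dense_units=int(rng.integers(2, 10)),
                seed=int(rng.integers(0, 1000)),
            )
            L = int(rng.integers(4, 20))
            net = HybridNet(cfg, L, rng=np.random.default_rng(trial))
            # non-trivial normalization statistics
            net.bn_moving_mean = rng.normal(size=cfg.conv_filters)
            net.bn_moving_var = rng.uniform(0.5, 2.0, size=cfg.conv_filters)
            x = rng.random(L)
            engine = net.forward(x[None, :], training=False)[0]
            ref = reference_forward(net.state_dict(), cfg, x)
            assert np.abs(engine - ref).max() < 1e-4

    def test_saturated_update_gate_hands_state_to_candidate(self):
        """With z_t pinned at 1, the final hidden state equals the
        candidate state exactly (the convex-combination limit)."""
        cfg = ModelConfig(conv_filters=3, gru_units=4, dense_units=2)
        net = HybridNet(cfg, 8, rng=np.random.default_rng(0))
        W = net.state_dict()
        W["gru_Wz"][:] = 0.0
        W["gru_Uz"][:] = 0.0
        W["gru_bz"][:] = 1000.0  # sigmoid(1000) == 1.0 in float64
        assert sigmoid(np.array([1000.0]))[0] == 1.0
        net.load_state_dict(W)
        x = np.random.default_rng(1).random(8)
        net.forward(x[None, :])
        # replay the recursion: h_t must equal tanh candidate at every step
        for x_t, h_prev, z, r, hc in net._cache["gru_steps"]:
            assert (z == 1.0).all()
        x_t, h_prev, z, r, hc = net._cache["gru_steps"][-1]
        h_last = net._cache["h_last"]
        assert (h_last == hc).all()

    def test_sigma_zero_is_half(self):
        assert sigmoid(np.array([0.0]))[0] == 0.5


class TestMetrics:
    def test_reconstructed_confusion_example(self):
        y_true = np.array([1] * 46 + [0] * 44)
        y_pred = np.array([1] * 45 + [0] * 1 + [0] * 44)  # TP=45 FN=1 TN=44 FP=0
        m = compute_metrics(y_true, y_pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (45, 1, 44, 0)
        assert round(m.accuracy, 2) == 98.89   # 89/90
        assert m.precision == 100.0            # 45/45
        assert round(m.recall, 2) == 97.83     # 45/46

    def test_perfect_classifier(self):
        m = compute_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert m.accuracy == m.precision == m.recall == m.f1 == 100.0

    def test_symmetric_confusion(self):
        m = compute_metrics([1, 1, 0, 0], [1, 0, 1, 0])  # TP=FP=FN=TN=1
        assert m.accuracy == m.precision == m.recall == m.f1 == 50.0

    def test_matches_bruteforce_on_random_cases(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(2, 60))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            m = compute_metrics(y_true, y_pred)
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
            tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
            fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
            fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
            assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
            assert m.accuracy == pytest.approx(100 * (tp + tn) / n)
            assert m.precision == pytest.approx(100 * tp / (tp + fp) if tp + fp else 0.0)
            assert m.recall == pytest.approx(100 * tp / (tp + fn) if tp + fn else 0.0)
            pr, rc = m.precision, m.recall
            assert m.f1 == pytest.approx(2 * pr * rc / (pr + rc) if pr + rc else 0.0)


@pytest.fixture(scope="module")
def toy_bundle(toy_training_set):
    X, y = toy_training_set
    cfg = ModelConfig.compact(epochs=6)
    bundle, X_test, y_test = train(X, y, config=cfg)
    return bundle, X_test, y_test


class TestTraining:
    def test_separable_data_high_accuracy(self, toy_bundle):
        bundle, X_test, y_test = toy_bundle
        m = evaluate(bundle, X_test, y_test)
        assert m.accuracy >= 98.0
        assert bundle.history["accuracy"].iloc[-1] >= 0.98

    def test_training_is_deterministic(self, toy_training_set):
        X, y = toy_training_set
        cfg = ModelConfig.compact(epochs=2)
        b1, _, _ = train(X, y, config=cfg)
        b2, _, _ = train(X, y, config=cfg)
        pd.testing.assert_frame_equal(b1.history, b2.history)
        for k in b1.weights:
            assert (b1.weights[k] == b2.weights[k]).all()

    def test_protocol_recorded_in_bundle(self, toy_bundle):
        bundle, _, _ = toy_bundle
        assert bundle.config.batch_size == 32
        assert bundle.config.epochs == 6
        assert len(bundle.history) <= bundle.config.epochs
        assert len(bundle.test_ids) > 0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((20, 10))
        with pytest.raises(TrainingError):
            train(X, np.zeros(20, dtype=int))

    def test_label_permutation_gives_chance_accuracy(self, toy_training_set):
        """No leakage: training on permuted labels cannot beat chance."""
        X, y = toy_training_set
        y_perm = np.random.default_rng(5).permutation(y)
        cfg = ModelConfig.compact(epochs=5)
        bundle, X_test, y_test = train(X, y_perm, config=cfg)
        m = evaluate(bundle, X_test, y_test)
        assert 35.0 <= m.accuracy <= 65.0

    def test_empty_test_set_rejected(self, toy_bundle):
        bundle, _, _ = toy_bundle
        with pytest.raises(EvaluationError):
            evaluate(bundle, np.empty((0, 20)), np.empty(0, dtype=int))

    def test_bundle_roundtrips_through_disk(self, toy_bundle, tmp_path):
        bundle, X_test, y_test = toy_bundle
        bundle.save(tmp_path / "bundle")
        back = ModelBundle.load(tmp_path / "bundle")
        assert back.gene_order == bundle.gene_order
        assert back.config == bundle.config
        p1 = bundle.predict_proba(X_test)
        p2 = back.predict_proba(X_test)
        assert np.allclose(p1, p2)


class TestSearch:
    def test_budget_one_returns_single_config(self, toy_training_set):
        X, y = toy_training_set
        space = SearchSpace(budget=1)
        best, log = hyperparameter_search(space, X[::4], y[::4], seed=0, trial_epochs=1)
        assert len(log) == 1
        assert best.conv_filters == log.loc[0, "conv_filters"]

    def test_samples_lie_on_published_grids(self):
        from gcgrader.net.search import sample_config

        rng = np.random.default_rng(0)
        space = SearchSpace()
        filters = set(range(16, 129, 4))
        gru = set(range(16, 129, 4))
        dense = set(range(16, 257, 4))
        dropouts = {round(0.1 * k, 10) for k in range(1, 6)}
        for _ in range(200):
            cfg = sample_config(space, rng)
            assert cfg.conv_filters in filters
            assert cfg.gru_units in gru
            assert cfg.dense_units in dense
            assert round(cfg.conv_dropout, 10) in dropouts
            assert 1e-4 <= cfg.learning_rate <= 1e-2

    def test_best_is_argmin_of_validation_loss(self, toy_training_set):
        X, y = toy_training_set
        space = SearchSpace(budget=5)
        best, log = hyperparameter_search(space, X[::4], y[::4], seed=3, trial_epochs=1)
        assert log["val_loss"].min() == log.loc[log["val_loss"].idxmin(), "val_loss"]
        best_row = log.loc[log["val_loss"].idxmin()]
        assert best.conv_filters == best_row["conv_filters"]
        assert (log["val_loss"] >= best_row["val_loss"]).all()


class TestSaliency:
    def test_scores_normalized_and_track_perturbation_importance(self):
        """Saliency must rank genes consistently with the model's measured
        sensitivity: shuffling a gene's column perturbs the predicted-class
        probability roughly in proportion to the gene's saliency (the
        architecture has positional structure — recurrent gradients decay
        toward early positions and conv weights are shared — so the honest
        oracle is this perturbation importance, which shares it)."""
        rng = np.random.default_rng(4)
        n, L = 300, 20
        informative = [6, 12, 18]
        X = rng.normal(0.5, 0.1, size=(2 * n, L))
        y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
        for j in informative:
            X[y == 1, j] += 0.35
        X = np.clip(X, 0, 1)
        genes = [f"g{i}" for i in range(L)]
        bundle, _, _ = train(X, y, config=ModelConfig.compact(epochs=6), gene_order=genes)
        table = saliency(bundle, X)
        assert table["saliency"].sum() == pytest.approx(1.0)
        assert (table["saliency"] >= 0).all()

        base = bundle.predict_proba(X)[:, 1]
        importance = np.zeros(L)
        shuffle_rng = np.random.default_rng(0)
        for j in range(L):
            Xp = X.copy()
            Xp[:, j] = shuffle_rng.permutation(Xp[:, j])
            importance[j] = np.abs(bundle.predict_proba(Xp)[:, 1] - base).mean()
        sal = table.set_index("gene")["saliency"].reindex(genes).to_numpy()
        from scipy.stats import spearmanr

        rho = spearmanr(sal, importance).statistic
        assert rho > 0.5

    def test_untrained_bundle_rejected(self):
        bundle = ModelBundle(
            config=ModelConfig(), input_length=5, weights=None,
            gene_order=list("abcde"), scaler=None, history=pd.DataFrame(),
        )
        with pytest.raises(ParameterError):
            saliency(bundle, np.zeros((2, 5)))
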