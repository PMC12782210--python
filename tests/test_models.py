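"""Classical grid-searched classifiers and the dual-stream transformer."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, make_scorer
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from motionid import (
    HyperparameterGrid,
    TransformerConfig,
    compute_metrics,
    fit_classical,
    fit_swipeformer,
    predict,
)
from motionid.models import FittedModel
from motionid._autodiff import Tensor


def gaussian_clouds(n_per_class=60, n_features=8, gap=8.0, seed=0):
    """Two well-separated clouds: target (1) vs rest (0)."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(gap, 1.0, (n_per_class, n_features))
    neg = rng.normal(0.0, 1.0, (n_per_class, n_features))
    X = np.vstack([pos, neg])
    y = np.r_[np.ones(n_per_class), np.zeros(n_per_class)].astype(int)
    return X, y


class TestFitClassical:
    @pytest.mark.parametrize("kind", ["knn", "rf", "nn"])
    def test_separable_clouds_training_f1_is_one(self, kind):
        X, y = gaussian_clouds()
        grid = HyperparameterGrid(knn_k=(5, 10), nn_l2_alpha=(1e-3,))
        model = fit_classical(kind, X, y, grid=grid, seed=0)
        decisions, _ = predict(model, X)
        assert compute_metrics(y, decisions).f1 == 1.0

    def test_single_class_labels_rejected(self):
        X, _ = gaussian_clouds()
        with pytest.raises(ValueError, match="single class"):
            fit_classical("knn", X, np.zeros(len(X), dtype=int))

    def test_single_setting_grid_equals_direct_fit(self):
        """A one-point grid must reproduce fitting that setting directly."""
        X, y = gaussian_clouds(gap=2.0, seed=3)
        grid = HyperparameterGrid(rf_max_depth=(10,))
        model = fit_classical("rf", X, y, grid=grid, seed=7)
        from sklearn.ensemble import RandomForestClassifier

        direct = RandomForestClassifier(
            n_estimators=100, max_depth=10, random_state=7
        ).fit(X, y)
        _, scores = predict(model, X)
        assert model.chosen_hyperparameters == {"max_depth": 10}
        assert np.allclose(scores, direct.predict_proba(X)[:, 1])

    def test_knn_grid_search_matches_sklearn_gridsearchcv(self):
        """Dual route: the shared-neighbor CV scores equal sklearn's search."""
        X, y = gaussian_clouds(n_per_class=45, gap=1.5, seed=5)
        grid = HyperparameterGrid(knn_k=(3, 7, 15))
        model = fit_classical("knn", X, y, grid=grid, seed=0)
        ref = GridSearchCV(
            KNeighborsClassifier(algorithm="brute"),
            {"n_neighbors": [3, 7, 15]},
            scoring=make_scorer(f1_score, zero_division=0),
            cv=StratifiedKFold(3, shuffle=False),
        ).fit(X, y)
        ours = {r["setting"]["n_neighbors"]: r["mean_cv_f1"] for r in model.cv_results}
        for k, score in zip(ref.cv_results_["param_n_neighbors"],
                            ref.cv_results_["mean_test_score"]):
            assert ours[int(k)] == pytest.approx(score, abs=1e-12)
        assert model.chosen_hyperparameters == ref.best_params_

    def test_oversized_k_skipped_with_warning(self):
        X, y = gaussian_clouds(n_per_class=30)
        with pytest.warns(UserWarning, match="skipping k"):
            model = fit_classical("knn", X, y, grid=HyperparameterGrid(), seed=0)
        assert model.chosen_hyperparameters["n_neighbors"] in (5, 10)

    def test_all_k_skipped_is_an_error(self):
        X, y = gaussian_clouds(n_per_class=4)
        grid = HyperparameterGrid(knn_k=(100, 200))
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="grid"):
            fit_classical("knn", X, y, grid=grid, seed=0)

    def test_selected_setting_dominates_grid(self):
        X, y = gaussian_clouds(n_per_class=60, gap=1.0, seed=9)
        model = fit_classical("knn", X, y, grid=HyperparameterGrid(knn_k=(3, 9, 27)), seed=0)
        best = model.chosen_hyperparameters["n_neighbors"]
        best_score = next(
            r["mean_cv_f1"] for r in model.cv_results
            if r["setting"]["n_neighbors"] == best
        )
        assert all(r["mean_cv_f1"] <= best_score for r in model.cv_results)

    def test_deterministic_given_seed(self):
        X, y = gaussian_clouds(gap=1.0, seed=2)
        a = fit_classical("rf", X, y, seed=5)
        b = fit_classical("rf", X, y, seed=5)
        _, sa = predict(a, X)
        _, sb = predict(b, X)
        assert np.array_equal(sa, sb)
        assert a.chosen_hyperparameters == b.chosen_hyperparameters


class TestPredict:
    def test_decisions_are_thresholded_scores(self):
        X, y = gaussian_clouds(gap=1.0)
        model = fit_classical("knn", X, y, grid=HyperparameterGrid(knn_k=(5,)), seed=0)
        decisions, scores = predict(model, X)
        assert np.array_equal(decisions, scores >= 0.5)

    def test_score_exactly_half_is_positive(self):
        est = KNeighborsClassifier(n_neighbors=2, algorithm="brute").fit(
            [[-1.0], [1.0]], [0, 1]
        )
        model = FittedModel(
            model_kind="knn", target_user_id="u", estimator=est,
            chosen_hyperparameters={"n_neighbors": 2},
        )
        decisions, scores = predict(model, [[0.0]])
        assert scores[0] == 0.5
        assert bool(decisions[0]) is True

    def test_feature_shape_mismatch_is_an_error(self):
        X, y = gaussian_clouds()
        model = fit_classical("knn", X, y, grid=HyperparameterGrid(knn_k=(5,)), seed=0)
        with pytest.raises(ValueError, match="features"):
            predict(model, X[:, :3])


def sinusoid_fixture(n=120, length=100, seed=0):
    """Target windows carry a 5 Hz sinusoid on one accel channel; rest noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 0.3, (n, length, 6))
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
    t = np.arange(length) / 100.0
    X[: n // 2, :, 3] += 0.5 * np.sin(2 * np.pi * 5.0 * t)
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestSwipeformer:
    def test_frequency_marked_target_detected_held_out(self):
        X, y = sinusoid_fixture()
        cfg = TransformerConfig(epochs=15, seed=1)
        model = fit_swipeformer(X[::2], y[::2], cfg)
        decisions, _ = predict(model, X[1::2])
        assert compute_metrics(y[1::2], decisions).f1 >= 0.95

    def test_zero_epochs_predicts_at_chance(self):
        X, y = sinusoid_fixture()
        model = fit_swipeformer(X, y, TransformerConfig(epochs=0, seed=2))
        decisions, scores = predict(model, X)
        f1 = compute_metrics(y, decisions).f1
        base = y.mean()
        all_positive_f1 = 2 * base / (1 + base)
        assert f1 <= all_positive_f1 + 0.1  # cannot beat chance
        assert model.estimator.loss_history == []

    def test_seeded_determinism_of_training(self):
        X, y = sinusoid_fixture(n=40)
        cfg = TransformerConfig(epochs=3, seed=9, embedding_dim=8, mlp_hidden_sizes=(8,))
        a = fit_swipeformer(X, y, cfg)
        b = fit_swipeformer(X, y, cfg)
        assert a.estimator.loss_history == b.estimator.loss_history
        _, sa = predict(a, X)
        _, sb = predict(b, X)
        assert np.array_equal(sa, sb)

    def test_single_class_labels_rejected(self):
        X, y = sinusoid_fixture(n=20)
        with pytest.raises(ValueError, match="single class"):
            fit_swipeformer(X, np.zeros_like(y), TransformerConfig(epochs=1))

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="divisible"):
            TransformerConfig(embedding_dim=30, attention_heads=4)
        with pytest.raises(ValueError):
            TransformerConfig(conv_kernel=4)


class TestAutodiff:
    """Numerical gradient checks for the hand-rolled reverse-mode engine."""

    @staticmethod
    def numeric_grad(fn, x, eps=1e-6):
        g = np.zeros_like(x.data)
        flat = x.data.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn().data.item()
            flat[i] = orig - eps
            lo = fn().data.item()
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        return g

    def test_composite_graph_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        W = Tensor(rng.normal(size=(4, 4)), requires_grad=True)
        gamma = Tensor(np.ones(4), requires_grad=True)
        beta = Tensor(np.zeros(4), requires_grad=True)
        x = Tensor(rng.normal(size=(3, 5, 4)))

        def loss():
            h = (x @ W).softmax(axis=-1) @ W
            h = h.layer_norm(gamma, beta)
            return (h.relu().mean(axis=1) @ W).softplus().sum() * 0.1

        for p in (W, gamma, beta):
            want = self.numeric_grad(loss, p)
            out = loss()
            for q in (W, gamma, beta):
                q.zero_grad()
            out.backward()
            assert np.allclose(p.grad, want, atol=1e-6), p.shape

    def test_broadcast_add_and_mul_gradients(self):
        a = Tensor(np.arange(6.0).reshape(2, 3), requires_grad=True)
        b = Tensor(np.array([1.0, 2.0, 3.0]), requires_grad=True)

        def loss():
            return ((a * b + b) ** 2.0).sum()

        want_a = self.numeric_grad(loss, a)
        want_b = self.numeric_grad(loss, b)
        out = loss()
        a.zero_grad(), b.zero_grad()
        out.backward()
        assert np.allclose(a.grad, want_a, atol=1e-6)
        assert np.allclose(b.grad, want_b, atol=1e-6)

    def test_full_classifier_gradient(self):
        from motionid.transformer import DualStreamClassifier

        cfg = TransformerConfig(
            sequence_length=12, channels=3, conv_kernel=3, attention_heads=2,
            encoder_layers=1, embedding_dim=4, mlp_hidden_sizes=(4,),
            epochs=0, batch_size=8, seed=0,
        )
        clf = DualStreamClassifier(cfg)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 12, 3))
        y = np.array([1, 0, 1, 0, 1, 0], dtype=float)
        xt, ft = clf._prepare(X, fit=True)

        def loss():
            logits = clf._logits(xt, ft)
            yb = Tensor(y)
            return (yb * (-logits).softplus() + (1.0 - yb) * logits.softplus()).mean()

        for name in ("time.conv.W", "time.enc0.Wq", "freq.enc0.W1", "mlp.W0",
                     "time.enc0.ln1.g"):
            p = clf.params[name]
            want = self.numeric_grad(loss, p)
            out = loss()
            for q in clf.params.values():
                q.zero_grad()
            out.backward()
            assert np.allclose(p.grad, want, atol=1e-5), name
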