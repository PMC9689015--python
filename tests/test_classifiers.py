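import warnings

import numpy as np
import pytest

from crydiag.classifiers import (
    CryMlpClassifier,
    GridSpec,
    RbfSvmClassifier,
    grid_search,
    predict,
    train_mlp,
    train_svm,
)


def blobs(n=40, sep=6.0, d=2, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n // 2, d))
    b = rng.normal(sep, 1.0, (n // 2, d))
    X = np.vstack([a, b])
    y = np.array(["septic"] * (n // 2) + ["rds"] * (n // 2))
    return X, y


class TestSvm:
    def test_separable_blobs_perfect_training_accuracy(self):
        X, y = blobs()
        model = RbfSvmClassifier(gamma=0.25, C=1.0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_decision_invariant_to_row_order(self):
        X, y = blobs(seed=3)
        perm = np.random.default_rng(0).permutation(len(y))
        a = RbfSvmClassifier().fit(X, y)
        b = RbfSvmClassifier().fit(X[perm], y[perm])
        probe = np.random.default_rng(1).normal(2.0, 2.0, (20, 2))
        assert np.allclose(a.decision_function(probe), b.decision_function(probe),
                           atol=1e-5)
        assert np.array_equal(a.predict(probe), b.predict(probe))

    def test_large_gamma_overfits(self):
        # overlapping classes: huge gamma memorises training rows and
        # generalises toward chance on held-out rows
        X, y = blobs(n=60, sep=1.0, seed=5)
        Xv, yv = blobs(n=60, sep=1.0, seed=6)
        tight = RbfSvmClassifier(gamma=500.0, C=5.0).fit(X, y)
        smooth = RbfSvmClassifier(gamma=0.1, C=1.0).fit(X, y)
        assert np.mean(tight.predict(X) == y) == 1.0
        assert np.mean(tight.predict(Xv) == yv) < np.mean(smooth.predict(Xv) == yv)

    def test_single_class_raises(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            RbfSvmClassifier().fit(X, np.array(["septic"] * 5))

    def test_scores_in_unit_interval(self):
        X, y = blobs()
        model = train_svm(X, y, gamma=0.25, C=1.0)
        scores = model.class_scores(X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_width_mismatch_raises(self):
        X, y = blobs()
        model = RbfSvmClassifier().fit(X, y)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((3, 5)))


class TestMlp:
    def test_layer_widths_for_fused_input(self):
        X = np.random.default_rng(0).normal(size=(30, 17))
        y = np.array(["septic", "rds"] * 15)
        model = CryMlpClassifier(epochs=5).fit(X, y)
        W1, b1, W2, b2 = model.params_
        assert W1.shape == (17, 128) and W2.shape == (128, 2)

    def test_seeded_determinism(self):
        X, y = blobs(d=4)
        a = CryMlpClassifier(epochs=30, seed=9).fit(X, y)
        b = CryMlpClassifier(epochs=30, seed=9).fit(X, y)
        for pa, pb in zip(a.params_, b.params_):
            assert np.array_equal(pa, pb)
        assert np.array_equal(a.predict(X), b.predict(X))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separable_corpus_learns(self, seed):
        X, y = blobs(n=60, d=4, seed=seed)
        model = CryMlpClassifier(epochs=120, seed=seed).fit(X, y)
        losses = model.history_["train_loss"]
        assert losses[-1] < losses[0]
        assert np.mean(model.predict(X) == y) > 0.9

    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(7, 3))
        y_onehot = np.eye(2)[rng.integers(0, 2, 7)]
        net = CryMlpClassifier(hidden_width=5, l2=1e-3)
        params = [rng.normal(size=(3, 5)), rng.normal(size=5),
                  rng.normal(size=(5, 2)), rng.normal(size=2)]
        grads = net._gradients(X, y_onehot, params)
        eps = 1e-6
        for p_idx, p in enumerate(params):
            flat = p.ravel()
            for j in range(flat.size):
                orig = flat[j]
                flat[j] = orig + eps
                lp = net._loss(net._forward(X, params)[-1], y_onehot, params)
                flat[j] = orig - eps
                lm = net._loss(net._forward(X, params)[-1], y_onehot, params)
                flat[j] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[p_idx].ravel()[j] == pytest.approx(numeric, abs=2e-5)

    def test_strong_l2_shrinks_weights(self):
        X, y = blobs(n=40, d=4, seed=2)
        weak = CryMlpClassifier(epochs=60, l2=1e-4, seed=0).fit(X, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            strong = CryMlpClassifier(epochs=60, l2=10.0, seed=0).fit(X, y)
        assert np.linalg.norm(strong.params_[0]) < np.linalg.norm(weak.params_[0])

    def test_divergence_raises(self):
        X, y = blobs(d=2)
        with pytest.raises(FloatingPointError, match="diverged"):
            CryMlpClassifier(epochs=3, learning_rate=1e160).fit(X, y)

    def test_non_convergence_warns(self):
        X = np.zeros((20, 4))  # featureless input cannot be learned
        y = np.array(["septic", "rds"] * 10)
        with pytest.warns(RuntimeWarning, match="converge"):
            CryMlpClassifier(epochs=2, learning_rate=1e-9).fit(X, y)


class TestGridSearch:
    def test_svm_grid_has_25_combinations(self):
        X, y = blobs()
        Xv, yv = blobs(seed=1)
        best, table = grid_search(GridSpec(), "svm", X, y, Xv, yv)
        assert len(table) == 25

    def test_singleton_grid_returns_it(self):
        X, y = blobs()
        grid = GridSpec(svm_gamma=(0.3,), svm_C=(2.0,))
        best, table = grid_search(grid, "svm", X, y, X, y)
        assert best == {"C": 2.0, "gamma": 0.3}
        assert len(table) == 1

    def test_tie_break_prefers_earlier_ordering(self):
        # perfectly separable validation data: every combination ties at
        # accuracy 1, so the first in (C asc, gamma asc) order must win
        X, y = blobs(sep=12.0)
        best, table = grid_search(GridSpec(), "svm", X, y, X, y)
        assert table["val_accuracy"].max() == 1.0
        assert best == {"C": 0.5, "gamma": 0.1}

    def test_winner_matches_independent_re_evaluation(self):
        from itertools import product

        from sklearn.svm import SVC

        X, y = blobs(n=30, sep=1.4, seed=8)
        Xv, yv = blobs(n=30, sep=1.4, seed=9)
        grid = GridSpec()
        best, table = grid_search(grid, "svm", X, y, Xv, yv)
        # oracle: brute-force re-evaluation straight through sklearn
        oracle = []
        for C, g in product(sorted(grid.svm_C), sorted(grid.svm_gamma)):
            acc = SVC(kernel="rbf", gamma=g, C=C).fit(X, y).score(Xv, yv)
            oracle.append(((C, g), acc))
        best_oracle = max(oracle, key=lambda t: t[1])[1]
        winners = [cfg for cfg, acc in oracle if acc == best_oracle]
        assert (best["C"], best["gamma"]) == winners[0]
        assert np.allclose(table["val_accuracy"], [a for _, a in oracle])

    def test_mlp_grid_runs_and_reports(self):
        X, y = blobs(n=24, d=3, seed=1)
        grid = GridSpec(mlp_lr=(1e-3, 1e-2), mlp_l2=(1e-4,), mlp_epochs=(20,))
        best, table = grid_search(grid, "mlp", X, y, X, y, seed=0)
        assert len(table) == 2
        assert set(best) == {"learning_rate", "l2", "epochs"}


class TestPredictHelper:
    def test_labels_closed_set_and_scores_bounded(self):
        X, y = blobs()
        model = train_mlp(X, y, epochs=40, seed=1)
        labels, scores = predict(model, X, positive_class="septic")
        assert set(labels) <= {"septic", "rds"}
        assert np.all((scores >= 0) & (scores <= 1))

    def test_training_rows_consistency(self):
        X, y = blobs(sep=8.0)
        model = train_svm(X, y, gamma=0.25, C=1.0)
        labels, _ = predict(model, X)
        assert np.mean(labels == y) == 1.0
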