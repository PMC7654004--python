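"""Multilayer perceptron: forward/backward, loss, dropout, early stopping,
random architecture search."""

import numpy as np
import pytest

from gepred.nnet import (Architecture, EarlyStopper, MLPRegressor,
                         SearchSpace, TrainConfig, _backprop, _init_weights,
                         apply_dropout, forward, penalized_loss,
                         random_search, sample_architecture, train)


def _linear_data(rng, n=300, p=8, noise=0.0):
    Z = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = Z @ beta + noise * rng.normal(size=n)
    return Z, y, beta


class TestForward:
    def test_zero_weights_zero_output(self):
        arch = Architecture(2, (3, 2), 0.0, 1.0)
        w = [(np.zeros((4, 3)), np.zeros(3)), (np.zeros((3, 2)), np.zeros(2)),
             (np.zeros((2, 1)), np.zeros(1))]
        assert forward(arch, w, np.ones(4)) == 0.0

    def test_relu_gates_negative_preactivation(self):
        arch = Architecture(1, (1,), 0.0, 1.0)
        w = [(np.array([[-5.0]]), np.zeros(1)),
             (np.array([[3.0]]), np.zeros(1))]
        assert forward(arch, w, np.array([2.0])) == 0.0
        # positive pre-activation passes through
        assert forward(arch, w, np.array([-1.0])) == pytest.approx(15.0)

    def test_hand_computed_two_unit_net(self):
        # 2 inputs -> hidden (2 units, ReLU) -> linear output
        arch = Architecture(1, (2,), 0.0, 1.0)
        W1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        b1 = np.array([0.0, 0.5])
        W2 = np.array([[2.0], [-1.0]])
        b2 = np.array([0.25])
        w = [(W1, b1), (W2, b2)]
        x = np.array([1.0, 2.0])
        h = np.maximum(x @ W1 + b1, 0)          # (2.0, 3.5)
        expect = float((h @ W2 + b2)[0])        # 4 - 3.5 + 0.25 = 0.75
        assert forward(arch, w, x) == pytest.approx(expect)
        assert expect == pytest.approx(0.75)

    def test_predict_mode_deterministic_under_dropout_arch(self, rng):
        arch = Architecture(1, (8,), 0.0, 0.5)
        w = _init_weights(arch, 5, rng, 0.5)
        x = rng.normal(size=(7, 5))
        a = forward(arch, w, x, mode="predict")
        b = forward(arch, w, x, mode="predict")
        np.testing.assert_array_equal(a, b)


class TestLoss:
    def test_perfect_fit_zero_weights(self):
        y = np.array([1.0, 2.0])
        assert penalized_loss(y, y, [(np.zeros((2, 1)), np.zeros(1))], 5.0) == 0

    def test_residuals_only(self):
        assert penalized_loss([0, 0], [1, -1], [], 0.0) == 2.0

    def test_residuals_plus_penalty_arithmetic(self):
        w = [(np.array([[2.0]]), np.array([9.0]))]   # bias excluded
        got = penalized_loss([0, 0], [1, 2], w, 0.5)
        assert got == pytest.approx(1 + 4 + 0.5 * 4)


class TestDropout:
    def test_keep_one_identity(self, rng):
        a = rng.normal(size=100)
        np.testing.assert_array_equal(apply_dropout(a, 1.0, rng), a)

    def test_keep_fraction_binomial(self):
        rng = np.random.default_rng(0)
        a = np.ones(10_000)
        masked = apply_dropout(a, 0.5, rng)
        assert abs((masked > 0).mean() - 0.5) < 0.02

    def test_expectation_preserved(self):
        rng = np.random.default_rng(1)
        a = rng.normal(2.0, 1.0, 500)
        means = [apply_dropout(a, 0.7, rng).mean() for _ in range(1000)]
        assert np.mean(means) == pytest.approx(a.mean(), abs=0.02)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_dropout(np.ones(3), 0.0, rng)


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        arch = Architecture(2, (4, 3), l2_lambda=0.03, dropout_keep=1.0)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        w = [(W, rng.normal(0, 0.3, b.shape))
             for W, b in _init_weights(arch, 5, rng, 0.5)]
        # finite differences require clearance from the ReLU kinks
        from gepred.nnet import _forward_cache
        pre = _forward_cache(arch, w, X, "predict", None)[2]
        assert min(np.abs(p).min() for p in pre[:-1]) > 1e-4
        _, grads, _ = _backprop(arch, w, X, y)
        eps = 1e-6
        for k, (W, b) in enumerate(w):
            for arr, g in ((W, grads[k][0]), (b, grads[k][1])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp = penalized_loss(y, forward(arch, w, X), w,
                                        arch.l2_lambda)
                    arr[idx] = orig - eps
                    lm = penalized_loss(y, forward(arch, w, X), w,
                                        arch.l2_lambda)
                    arr[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert abs(fd - g[idx]) <= 1e-5 * max(1.0, abs(fd))


class TestEarlyStopping:
    def test_rigged_sequence_stops_after_five_bad_evaluations(self):
        stopper = EarlyStopper(patience=5)
        decisions = [stopper.update(m) for m in (5, 4, 4.1, 4.2, 4.3, 4.4, 4.5)]
        assert decisions == [False, False, False, False, False, False, True]
        assert stopper.best_index == 1 and stopper.best == 4

    def test_improvement_resets_patience(self):
        stopper = EarlyStopper(patience=3)
        seq = (5, 4.5, 4.6, 4.7, 4.0, 4.1, 4.2, 4.3)
        decisions = [stopper.update(m) for m in seq]
        assert decisions.index(True) == len(seq) - 1

    def test_returned_weights_match_best_evaluation(self):
        rng = np.random.default_rng(2)
        Z, y, _ = _linear_data(rng, noise=1.0)
        arch = Architecture(1, (4,), 0.0, 1.0)
        res = train(arch, (Z[:200], y[:200]), (Z[200:], y[200:]),
                    TrainConfig(learning_rate=1e-2, max_epochs=200, seed=0))
        pred = res.predict(Z[200:])
        mse = np.mean((y[200:] - pred) ** 2)
        assert mse == pytest.approx(min(res.history), rel=1e-9)

    def test_empty_tuning_set_rejected(self, rng):
        Z, y, _ = _linear_data(rng)
        with pytest.raises(ValueError, match="tuning"):
            train(Architecture(1, (2,), 0.0, 1.0), (Z, y),
                  (Z[:0], y[:0]), TrainConfig(max_epochs=5))


class TestTraining:
    def test_linear_net_recovers_least_squares(self):
        """One linear-regime hidden unit, no penalty, no dropout: the net's
        effective coefficients align with the OLS solution."""
        rng = np.random.default_rng(3)
        Z, y, beta = _linear_data(rng, n=400, p=6)
        arch = Architecture(1, (1,), 0.0, 1.0)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=1000, seed=4)
        res = train(arch, (Z, y), (Z[:80], y[:80]), cfg)
        mse = np.mean((y - res.predict(Z)) ** 2)
        assert mse < 0.01 * np.mean((y - y.mean()) ** 2)
        # effective linear map via finite differences around the origin
        x0 = np.zeros(6)
        f0 = forward(arch, res.weights, x0)
        coef = np.array([forward(arch, res.weights, x0 + 1e-3 * e) - f0
                         for e in np.eye(6)]) / 1e-3
        ols = np.linalg.lstsq(Z, y, rcond=None)[0]
        cosine = coef @ ols / (np.linalg.norm(coef) * np.linalg.norm(ols))
        assert cosine > 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_stronger_penalty_never_grows_weight_norm(self, seed):
        rng = np.random.default_rng(seed)
        Z, y, _ = _linear_data(rng, n=150, p=5, noise=0.5)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=60, seed=seed)
        norms = []
        for lam in (0.01, 0.1):
            arch = Architecture(1, (4,), lam, 1.0)
            res = train(arch, (Z[:100], y[:100]), (Z[100:], y[100:]), cfg)
            norms.append(sum(float(np.sum(W ** 2)) for W, _ in res.weights))
        assert norms[1] <= norms[0]

    def test_dropout_training_still_learns(self):
        rng = np.random.default_rng(5)
        Z, y, _ = _linear_data(rng, n=500, p=4, noise=0.3)
        arch = Architecture(1, (16,), 0.0, 0.8)
        res = train(arch, (Z[:400], y[:400]), (Z[400:], y[400:]),
                    TrainConfig(learning_rate=1e-2, max_epochs=150, seed=6))
        r = np.corrcoef(y[400:], res.predict(Z[400:]))[0, 1]
        assert r > 0.7


class TestRandomSearch:
    def test_single_candidate_wins(self, rng):
        Z, y, _ = _linear_data(rng)
        space = SearchSpace(layers=(1,), units=(4,), l2=(0.0,), dropout=(1.0,))
        best, board, res = random_search(
            space, 1, (Z[:200], y[:200]), (Z[200:], y[200:]),
            TrainConfig(learning_rate=1e-2, max_epochs=20), seed=0)
        assert len(board) == 1 and best.units_per_layer == (4,)

    def test_candidate_draws_reproducible(self):
        space = SearchSpace()
        a = [sample_architecture(space, np.random.default_rng(42))
             for _ in range(20)]
        b = [sample_architecture(space, np.random.default_rng(42))
             for _ in range(20)]
        assert a == b

    def test_candidates_drawn_from_grids(self):
        space = SearchSpace()
        rng = np.random.default_rng(0)
        for _ in range(50):
            arch = sample_architecture(space, rng)
            assert arch.n_hidden_layers in space.layers
            assert all(u in space.units for u in arch.units_per_layer)
            assert arch.l2_lambda in space.l2
            assert arch.dropout_keep in space.dropout

    def test_better_architecture_selected(self, rng):
        # a wide net trained properly vs a 1-unit net barely trained:
        # the leaderboard must rank by tuning correlation
        Z, y, _ = _linear_data(rng, n=300, p=5)
        space = SearchSpace(layers=(1,), units=(1, 16), l2=(0.0,),
                            dropout=(1.0,))
        best, board, _ = random_search(
            space, 6, (Z[:200], y[:200]), (Z[200:], y[200:]),
            TrainConfig(learning_rate=1e-2, max_epochs=40), seed=1)
        top = board.sort_values("tune_correlation", ascending=False).iloc[0]
        assert str(best.units_per_layer[0]) == top["units"]


class TestModelObject:
    def test_fit_and_summary(self, rng):
        Z, y, _ = _linear_data(rng, n=200, p=4, noise=0.5)
        model = MLPRegressor(y[:150], Z[:150], y[150:], Z[150:])
        res = model.fit(Architecture(1, (4,), 0.0, 1.0),
                        TrainConfig(learning_rate=1e-2, max_epochs=30))
        text = res.summary()
        assert "tuning MSE" in text and "architecture" in text
        assert len(res.predict(Z)) == 200

    def test_architecture_validation(self):
        with pytest.raises(ValueError):
            Architecture(2, (4,), 0.0, 1.0)       # wrong units length
        with pytest.raises(ValueError):
            Architecture(1, (4,), -0.1, 1.0)      # negative penalty
        with pytest.raises(ValueError):
            Architecture(1, (4,), 0.0, 0.0)       # zero keep-rate
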