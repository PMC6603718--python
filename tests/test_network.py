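"""Network forward/gradient correctness and training-algorithm contracts."""

import numpy as np
import pytest

from hydrofuse.network import (
    NeuralNetRegressor,
    TrainingError,
    activation,
    activation_deriv,
    levenberg_marquardt,
)


class TestActivations:
    def test_logistic_values_and_derivative(self):
        assert activation("logistic", 0.0) == pytest.approx(0.5)
        assert activation_deriv("logistic", 0.0) == pytest.approx(0.25)

    def test_tanh_values_and_corrected_derivative(self):
        assert activation("tanh", 0.0) == pytest.approx(0.0)
        assert activation_deriv("tanh", 0.0) == pytest.approx(1.0)
        # derivative is 1 - tanh(x)^2 at every x, not 1/(x^2+1)
        x = np.linspace(-3, 3, 13)
        assert np.allclose(activation_deriv("tanh", x), 1 - np.tanh(x) ** 2)

    def test_relu_cases(self):
        assert activation("relu", -3.0) == 0.0
        assert activation("relu", 2.0) == 2.0
        assert activation_deriv("relu", -1.0) == 0.0
        assert activation_deriv("relu", 0.0) == 1.0  # tie-break at the kink

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown activation"):
            activation("softsign", 1.0)


class TestInitialization:
    def test_same_seed_identical_weights(self, rng):
        x, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        nets = [
            NeuralNetRegressor(hidden_layer_sizes=(5, 4), max_epochs=0,
                               random_state=7).fit(x, y)
            for _ in range(2)
        ]
        for w1, w2 in zip(nets[0].weights_, nets[1].weights_):
            assert np.array_equal(w1, w2)

    def test_different_seeds_differ(self, rng):
        x, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        a = NeuralNetRegressor(max_epochs=0, random_state=1).fit(x, y)
        b = NeuralNetRegressor(max_epochs=0, random_state=2).fit(x, y)
        assert not np.array_equal(a.weights_[0], b.weights_[0])

    def test_fan_in_scaling(self):
        rng = np.random.default_rng(0)
        sds = {}
        for fan_in in (4, 100):
            draws = [
                NeuralNetRegressor(
                    hidden_layer_sizes=(3, 3), max_epochs=0, random_state=s
                )
                .fit(rng.normal(size=(5, fan_in)), rng.normal(size=5))
                .weights_[0]
                for s in range(100)
            ]
            sds[fan_in] = np.std(np.concatenate([d.ravel() for d in draws]))
        ratio = sds[4] / sds[100]
        assert ratio == pytest.approx(np.sqrt(100 / 4), rel=0.15)


def manual_net(weights, biases, x_mean, x_scale, y_mean, y_scale, acts):
    net = NeuralNetRegressor(
        hidden_layer_sizes=(len(biases[0]), len(biases[1])), activations=acts
    )
    net.weights_ = [np.asarray(w, float) for w in weights]
    net.biases_ = [np.asarray(b, float) for b in biases]
    net.layer_sizes_ = (weights[0].shape[0], len(biases[0]), len(biases[1]), 1)
    net.x_mean_, net.x_scale_ = np.asarray(x_mean, float), np.asarray(x_scale, float)
    net.y_mean_, net.y_scale_ = y_mean, y_scale
    return net


class TestForward:
    def test_zero_weights_predict_destandardized_bias(self, rng):
        x = rng.normal(size=(8, 3))
        net = manual_net(
            [np.zeros((3, 2)), np.zeros((2, 2)), np.zeros((2, 1))],
            [np.zeros(2), np.zeros(2), np.array([0.5])],
            np.zeros(3), np.ones(3), 10.0, 4.0,
            ("tanh", "tanh"),
        )
        # logistic/tanh of 0 = 0 -> output = bias 0.5 -> 10 + 4*0.5
        assert np.allclose(net.predict(x), 12.0)

    def test_hand_computed_two_by_two_net(self):
        w1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([[2.0, 0.0], [1.0, 1.0]])
        b2 = np.array([0.0, 0.3])
        w3 = np.array([[1.5], [-0.5]])
        b3 = np.array([0.2])
        net = manual_net(
            [w1, w2, w3], [b1, b2, b3], np.zeros(2), np.ones(2), 0.0, 1.0,
            ("logistic", "tanh"),
        )
        x = np.array([[0.3, -0.7], [1.2, 0.4]])
        a1 = 1 / (1 + np.exp(-(x @ w1 + b1)))
        a2 = np.tanh(a1 @ w2 + b2)
        expected = (a2 @ w3 + b3).ravel()
        assert np.allclose(net.predict(x), expected, atol=1e-12)

    def test_single_node_relu_pathway_reproduces_affine_map(self):
        # pre-activations kept positive, so relu is exactly linear
        net = manual_net(
            [np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]])],
            [np.array([10.0]), np.array([0.0]), np.array([-10.0])],
            np.array([0.0]), np.ones(1), 2.0, 3.0,
            ("relu", "relu"),
        )
        x = np.linspace(-2, 2, 9)[:, None]
        assert np.allclose(net.predict(x), 3.0 * x.ravel() + 2.0, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        x, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        net = NeuralNetRegressor(max_epochs=0, random_state=0).fit(x, y)
        with pytest.raises(ValueError, match="features"):
            net.predict(rng.normal(size=(3, 5)))


def finite_difference_gradient(net, xs, ys, h=1e-6):
    flat = net._get_flat().copy()
    grad = np.zeros_like(flat)
    for i in range(flat.size):
        for sign in (+1, -1):
            probe = flat.copy()
            probe[i] += sign * h
            net._set_flat(probe)
            yhat, _ = net._forward_std(xs)
            r = yhat - ys
            grad[i] += sign * 0.5 * float(r @ r)
    net._set_flat(flat)
    return grad / (2 * h)


class TestGradient:
    @pytest.mark.parametrize("acts,seed", [
        (("logistic", "logistic"), 10), (("tanh", "tanh"), 11),
        (("relu", "relu"), 12), (("logistic", "tanh"), 13),
    ])
    def test_backprop_matches_central_differences(self, acts, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(6, 3)), rng.normal(size=6)
        net = NeuralNetRegressor(
            hidden_layer_sizes=(4, 3), activations=acts, max_epochs=0,
            random_state=3,
        ).fit(x, y)
        xs = (x - net.x_mean_) / net.x_scale_
        ys = (y - net.y_mean_) / net.y_scale_
        analytic = net.gradient(x, y)
        numeric = finite_difference_gradient(net, xs, ys)
        denom = np.linalg.norm(analytic) + 1e-12
        assert np.linalg.norm(analytic - numeric) / denom < 1e-6

    def test_gradient_zero_at_perfect_fit(self, rng):
        x = rng.normal(size=(12, 2))
        net = NeuralNetRegressor(
            hidden_layer_sizes=(3, 2), max_epochs=0, random_state=5
        ).fit(x, np.zeros(12))
        y_self = net.predict(x)  # target = current predictions
        # y scaling was fit on zeros; emulate perfect fit in standardized space
        xs = (x - net.x_mean_) / net.x_scale_
        yhat, _ = net._forward_std(xs)
        grad, r = net._backprop(xs, yhat)
        assert np.allclose(r, 0.0)
        assert np.allclose(grad, 0.0, atol=1e-14)
        assert y_self.shape == (12,)


class TestLevenbergMarquardt:
    def test_quadratic_toy_reaches_analytic_minimum(self):
        # r(w) = w - 3: loss 0.5(w-3)^2, minimum at w = 3
        w, trace = levenberg_marquardt(
            lambda w: np.array([w[0] - 3.0]),
            lambda w: np.array([[1.0]]),
            np.array([0.0]),
        )
        assert abs(w[0] - 3.0) < 1e-6
        assert len(trace) - 1 <= 5  # accepted steps

    def test_accepted_losses_non_increasing(self, rng):
        x = rng.normal(size=(25, 3))
        y = np.sin(x[:, 0]) + 0.5 * x[:, 1]
        net = NeuralNetRegressor(
            hidden_layer_sizes=(6, 5), activations=("tanh", "tanh"),
            max_epochs=40, random_state=0,
        ).fit(x, y)
        assert np.all(np.diff(net.loss_trace_) <= 0)

    def test_noiseless_linear_task_converges(self, rng):
        x = rng.normal(size=(40, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + 4.0
        net = NeuralNetRegressor(
            hidden_layer_sizes=(5, 4), activations=("tanh", "tanh"),
            max_epochs=200, random_state=1,
        ).fit(x, y)
        rmse_std = np.sqrt(np.mean((net.predict(x) - y) ** 2)) / y.std()
        assert rmse_std < 1e-3


class TestTraining:
    def test_zero_epochs_returns_initial_network(self, rng):
        x, y = rng.normal(size=(10, 3)), rng.normal(size=10)
        trained = NeuralNetRegressor(max_epochs=0, random_state=11).fit(x, y)
        fresh = NeuralNetRegressor(max_epochs=0, random_state=11).fit(x, y)
        for a, b in zip(trained.weights_, fresh.weights_):
            assert np.array_equal(a, b)
        assert trained.loss_trace_ == []

    def test_training_reproducible_bit_for_bit(self, rng):
        x = rng.normal(size=(30, 4))
        y = x @ np.array([1.0, 0.5, -1.0, 2.0])
        fits = [
            NeuralNetRegressor(
                hidden_layer_sizes=(6, 5), max_epochs=25, random_state=21
            ).fit(x, y)
            for _ in range(2)
        ]
        for a, b in zip(fits[0].weights_, fits[1].weights_):
            assert np.array_equal(a, b)
        assert fits[0].loss_trace_ == fits[1].loss_trace_

    def test_backprop_mode_reduces_loss(self, rng):
        x = rng.normal(size=(40, 2))
        y = x @ np.array([2.0, -1.0])
        net = NeuralNetRegressor(
            hidden_layer_sizes=(4, 3), activations=("tanh", "tanh"),
            algorithm="backprop", learning_rate=0.05, momentum=0.9,
            max_epochs=500, random_state=2,
        ).fit(x, y)
        assert net.loss_trace_[-1] < 0.2 * net.loss_trace_[0]

    def test_backprop_divergence_raises_with_trace(self, rng):
        x = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        with pytest.raises(TrainingError) as exc:
            NeuralNetRegressor(
                algorithm="backprop", learning_rate=1e6, momentum=0.0,
                max_epochs=200, random_state=0,
            ).fit(x, y)
        assert len(exc.value.trace) >= 1

    def test_smooth_function_approximation(self, rng):
        """Universal-approximation smoke test: sin on [-3, 3], R^2 >= 0.99."""
        x = np.linspace(-3, 3, 200)[:, None]
        y = np.sin(x[:, 0])
        net = NeuralNetRegressor(
            hidden_layer_sizes=(10, 8), activations=("tanh", "tanh"),
            max_epochs=150, random_state=4,
        ).fit(x, y)
        resid = y - net.predict(x)
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 >= 0.99

    def test_invalid_config_rejected(self, rng):
        x, y = rng.normal(size=(10, 2)), rng.normal(size=10)
        with pytest.raises(ValueError):
            NeuralNetRegressor(algorithm="adam").fit(x, y)
        with pytest.raises(ValueError):
            NeuralNetRegressor(learning_rate=0.0, algorithm="backprop").fit(x, y)
        with pytest.raises(ValueError):
            NeuralNetRegressor(activations=("tanh", "step")).fit(x, y)
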