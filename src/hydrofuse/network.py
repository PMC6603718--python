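"""Feed-forward regression network with backprop and Levenberg-Marquardt.

A four-layer perceptron (input, two hidden layers, linear output) written
directly on numpy.  The hidden activations are the classical sensor-
calibration trio — logistic, tanh and ReLU — and training is either
full-batch gradient descent with momentum or Levenberg-Marquardt (LM) on
the residual vector, the standard small-network trainer:

    delta_w = -(J'J + lambda I)^-1 J' r

with the damping factor lambda decreased after an accepted step and
increased after a rejected one, so the accepted-step loss sequence is
non-increasing by construction.

Inputs and the response are z-standardized inside the model and the
scalers stored with it, so a fitted network predicts in original units
with no external bookkeeping.  All weight initialisation and training is
reproducible under ``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "activation",
    "activation_deriv",
    "levenberg_marquardt",
    "NeuralNetRegressor",
    "TrainingError",
]

SUPPORTED_ACTIVATIONS = ("logistic", "tanh", "relu")


class TrainingError(RuntimeError):
    """Training diverged; carries the loss trace up to the failure."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


def activation(tag: str, x):
    """Apply a supported activation elementwise.

    logistic 1/(1+e^-x); tanh 2/(1+e^-2x) - 1 (the hyperbolic tangent);
    relu max(0, x).
    """
    x = np.asarray(x, dtype=float)
    if tag == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    if tag == "tanh":
        return np.tanh(x)
    if tag == "relu":
        return np.maximum(x, 0.0)
    raise ValueError(f"unknown activation {tag!r}; supported: {SUPPORTED_ACTIVATIONS}")


def activation_deriv(tag: str, x):
    """Derivative of an activation at pre-activation x.

    logistic f(1-f); tanh 1 - f^2; relu the indicator of x >= 0 (the
    value at exactly 0 is a measure-zero tie-break, defined as 1).
    """
    x = np.asarray(x, dtype=float)
    if tag == "logistic":
        f = activation("logistic", x)
        return f * (1.0 - f)
    if tag == "tanh":
        f = np.tanh(x)
        return 1.0 - f * f
    if tag == "relu":
        return np.where(x >= 0, 1.0, 0.0)
    raise ValueError(f"unknown activation {tag!r}; supported: {SUPPORTED_ACTIVATIONS}")


def levenberg_marquardt(
    residual_fn,
    jacobian_fn,
    w0,
    *,
    lambda0: float = 1e-3,
    lambda_up: float = 10.0,
    lambda_down: float = 0.1,
    lambda_max: float = 1e12,
    max_steps: int = 1000,
    tol: float = 1e-9,
    patience: int = 20,
):
    """Minimise 0.5*||r(w)||^2 by damped Gauss-Newton steps.

    Returns ``(w, trace)`` where ``trace`` holds the loss at w0 followed
    by the loss after every *accepted* step (hence non-increasing).
    Stops when no step can be accepted before ``lambda`` exceeds
    ``lambda_max``, or when the improvement over the last ``patience``
    accepted steps falls below ``tol``.
    """
    w = np.asarray(w0, dtype=float).copy()
    r = residual_fn(w)
    loss = 0.5 * float(r @ r)
    if not np.isfinite(loss):
        raise TrainingError("non-finite loss at the initial point", [loss])
    trace = [loss]
    lam = float(lambda0)
    eye = np.eye(w.size)
    for _ in range(max_steps):
        jac = jacobian_fn(w)
        grad = jac.T @ r
        hess = jac.T @ jac
        accepted = False
        while lam <= lambda_max:
            try:
                delta = np.linalg.solve(hess + lam * eye, grad)
            except np.linalg.LinAlgError:
                lam *= lambda_up
                continue
            w_try = w - delta
            r_try = residual_fn(w_try)
            loss_try = 0.5 * float(r_try @ r_try)
            if np.isfinite(loss_try) and loss_try < loss:
                w, r, loss = w_try, r_try, loss_try
                accepted = True
                lam = max(lam * lambda_down, 1e-14)
                break
            lam *= lambda_up
        if not accepted:
            break
        trace.append(loss)
        if len(trace) > patience and trace[-patience - 1] - trace[-1] < tol:
            break
    return w, trace


class NeuralNetRegressor(RegressorMixin, BaseEstimator):
    """Two-hidden-layer feed-forward net for scalar calibration targets.

    Parameters
    ----------
    hidden_layer_sizes : (int, int)
        Node counts of the two hidden layers.
    activations : (str, str)
        Hidden-layer activations, each in {"logistic", "tanh", "relu"};
        the output node is always linear.
    algorithm : {"lm", "backprop"}
        Levenberg-Marquardt (default) or full-batch gradient descent with
        momentum.  ``learning_rate``/``momentum`` apply only to backprop.
    max_epochs : int
        Training iterations (accepted LM steps / gradient epochs); 0
        returns the initialised, untrained network.
    tol, patience : float, int
        Early stop when the loss improves by less than ``tol`` over
        ``patience`` consecutive epochs.
    random_state : int or None
        Seed for weight initialisation (N(0, 1/fan_in) weights, zero
        biases).

    Attributes
    ----------
    weights_, biases_ : lists of per-layer arrays.
    loss_trace_ : list of accepted-step losses, 0.5*sum(r^2) in
        standardized units.
    x_mean_, x_scale_, y_mean_, y_scale_ : stored standardizers.
    """

    def __init__(
        self,
        hidden_layer_sizes=(30, 25),
        activations=("logistic", "tanh"),
        algorithm: str = "lm",
        learning_rate: float = 0.001,
        momentum: float = 0.9,
        max_epochs: int = 1000,
        tol: float = 1e-9,
        patience: int = 20,
        lm_lambda0: float = 1e-3,
        lm_lambda_up: float = 10.0,
        lm_lambda_down: float = 0.1,
        random_state=None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activations = activations
        self.algorithm = algorithm
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.tol = tol
        self.patience = patience
        self.lm_lambda0 = lm_lambda0
        self.lm_lambda_up = lm_lambda_up
        self.lm_lambda_down = lm_lambda_down
        self.random_state = random_state

    # -- parameter vector plumbing -------------------------------------

    def _layer_dims(self, n_features: int):
        h = tuple(int(v) for v in self.hidden_layer_sizes)
        if len(h) != 2 or any(v < 1 for v in h):
            raise ValueError("hidden_layer_sizes must be two positive counts")
        return (n_features, h[0], h[1], 1)

    def _init_weights(self, dims, rng):
        weights, biases = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), (fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return weights, biases

    def _get_flat(self):
        return np.concatenate(
            [w.ravel() for w in self.weights_] + [b.ravel() for b in self.biases_]
        )

    def _set_flat(self, flat):
        pos = 0
        for i, w in enumerate(self.weights_):
            self.weights_[i] = flat[pos : pos + w.size].reshape(w.shape)
            pos += w.size
        for i, b in enumerate(self.biases_):
            self.biases_[i] = flat[pos : pos + b.size].reshape(b.shape)
            pos += b.size

    # -- forward / backward --------------------------------------------

    def _forward_std(self, xs):
        """Forward pass in standardized space; returns (yhat, cache)."""
        acts = [xs]
        pres = []
        a = xs
        tags = list(self.activations) + [None]  # linear output
        for w, b, tag in zip(self.weights_, self.biases_, tags):
            z = a @ w + b
            pres.append(z)
            a = z if tag is None else activation(tag, z)
            acts.append(a)
        return acts[-1][:, 0], (acts, pres)

    def _backprop(self, xs, ys):
        """Gradient of 0.5*sum(residual^2) w.r.t. the flat parameters."""
        yhat, (acts, pres) = self._forward_std(xs)
        r = yhat - ys
        delta = r[:, None]  # linear output layer
        grads_w, grads_b = [None] * 3, [None] * 3
        for layer in (2, 1, 0):
            grads_w[layer] = acts[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights_[layer].T) * activation_deriv(
                    self.activations[layer - 1], pres[layer - 1]
                )
        flat = np.concatenate(
            [g.ravel() for g in grads_w] + [g.ravel() for g in grads_b]
        )
        return flat, r

    def _jacobian(self, xs):
        """Jacobian of predictions w.r.t. the flat parameters, shape (n, P)."""
        n = xs.shape[0]
        _, (acts, pres) = self._forward_std(xs)
        delta = np.ones((n, 1))
        jw, jb = [None] * 3, [None] * 3
        for layer in (2, 1, 0):
            jw[layer] = np.einsum("ni,nj->nij", acts[layer], delta).reshape(n, -1)
            jb[layer] = delta
            if layer > 0:
                delta = (delta @ self.weights_[layer].T) * activation_deriv(
                    self.activations[layer - 1], pres[layer - 1]
                )
        return np.concatenate(jw + jb, axis=1)

    # -- sklearn API ----------------------------------------------------

    def fit(self, X, y):
        x = np.atleast_2d(np.asarray(getattr(X, "intensity", X), dtype=float))
        yv = np.asarray(getattr(y, "conc", y), dtype=float).ravel()
        if x.shape[0] != yv.size:
            raise ValueError("X rows and y length differ")
        if x.shape[0] < 1:
            raise ValueError("need at least one training sample")
        for tag in self.activations:
            if tag not in SUPPORTED_ACTIVATIONS:
                raise ValueError(
                    f"unknown activation {tag!r}; supported: {SUPPORTED_ACTIVATIONS}"
                )
        if self.algorithm not in ("lm", "backprop"):
            raise ValueError("algorithm must be 'lm' or 'backprop'")
        if self.learning_rate <= 0 or not (0 <= self.momentum < 1):
            raise ValueError("need learning_rate > 0 and momentum in [0, 1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")

        self.x_mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        self.x_scale_ = np.where(sd > 0, sd, 1.0)
        self.y_mean_ = float(yv.mean())
        ysd = float(yv.std())
        self.y_scale_ = ysd if ysd > 0 else 1.0
        xs = (x - self.x_mean_) / self.x_scale_
        ys = (yv - self.y_mean_) / self.y_scale_

        rng = np.random.default_rng(self.random_state)
        dims = self._layer_dims(x.shape[1])
        self.weights_, self.biases_ = self._init_weights(dims, rng)
        self.layer_sizes_ = dims

        if self.max_epochs == 0:
            self.loss_trace_ = []
            self.n_iter_ = 0
            return self

        if self.algorithm == "lm":
            def residual(flat):
                self._set_flat(flat)
                yhat, _ = self._forward_std(xs)
                return yhat - ys

            def jacobian(flat):
                self._set_flat(flat)
                return self._jacobian(xs)

            w, trace = levenberg_marquardt(
                residual,
                jacobian,
                self._get_flat(),
                lambda0=self.lm_lambda0,
                lambda_up=self.lm_lambda_up,
                lambda_down=self.lm_lambda_down,
                max_steps=self.max_epochs,
                tol=self.tol,
                patience=self.patience,
            )
            self._set_flat(w)
            self.loss_trace_ = trace
            self.n_iter_ = len(trace) - 1
        else:
            velocity = np.zeros_like(self._get_flat())
            n = xs.shape[0]
            trace = []
            for epoch in range(self.max_epochs):
                grad, r = self._backprop(xs, ys)
                loss = 0.5 * float(r @ r)
                diverged = not np.isfinite(loss) or (
                    trace and loss > 1e12 * (trace[0] + 1e-300)
                )
                if diverged:
                    raise TrainingError(
                        f"backprop diverged at epoch {epoch}", trace
                    )
                trace.append(loss)
                velocity = self.momentum * velocity - self.learning_rate * grad / n
                self._set_flat(self._get_flat() + velocity)
                if (
                    len(trace) > self.patience
                    and trace[-self.patience - 1] - trace[-1] < self.tol
                ):
                    break
            self.loss_trace_ = trace
            self.n_iter_ = len(trace)
        return self

    def predict(self, X):
        if not hasattr(self, "weights_"):
            raise RuntimeError("NeuralNetRegressor is not fitted")
        x = np.atleast_2d(np.asarray(getattr(X, "intensity", X), dtype=float))
        if x.shape[1] != self.layer_sizes_[0]:
            raise ValueError(
                f"expected {self.layer_sizes_[0]} features, got {x.shape[1]}"
            )
        xs = (x - self.x_mean_) / self.x_scale_
        yhat, _ = self._forward_std(xs)
        return yhat * self.y_scale_ + self.y_mean_

    def gradient(self, X, y):
        """Flat gradient of 0.5*sum(residual^2) in standardized space.

        Exposed for verification against finite differences.
        """
        if not hasattr(self, "weights_"):
            raise RuntimeError("NeuralNetRegressor is not fitted")
        x = np.atleast_2d(np.asarray(getattr(X, "intensity", X), dtype=float))
        yv = np.asarray(getattr(y, "conc", y), dtype=float).ravel()
        xs = (x - self.x_mean_) / self.x_scale_
        ys = (yv - self.y_mean_) / self.y_scale_
        grad, _ = self._backprop(xs, ys)
        return grad
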