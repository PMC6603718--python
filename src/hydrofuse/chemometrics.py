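"""Latent-variable calibration: PCA, PCR and NIPALS-PLSR with k-fold CV.

The regression conventions follow standard chemometrics practice for
spectra: predictor columns are mean-centered but *not* variance-scaled
(all wavelengths share the same intensity unit), the response is
centered, and the number of latent components is chosen by k-fold
cross-validation on pooled out-of-fold predictions (default 10 folds).

R^2 here is always 1 - SSE/SST evaluated on the set being scored — not
the squared correlation — so a biased predictor is penalised even when
perfectly correlated with truth.  RMSE is in response units (mg/L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone

__all__ = [
    "Metrics",
    "score_metrics",
    "PCAScores",
    "fit_pca",
    "transform_scores",
    "PCRRegressor",
    "PLSRegressorNIPALS",
    "fit_pcr",
    "fit_plsr",
    "cross_validate_components",
]


@dataclass(frozen=True)
class Metrics:
    """Calibration/validation statistics of a predicted-vs-actual pairing.

    slope/offset are the OLS line of predicted on actual (an ideal model
    gives slope 1, offset 0).
    """

    r2: float
    rmse: float
    slope: float
    offset: float


def score_metrics(y_true, y_pred) -> Metrics:
    """R^2 (1 - SSE/SST), RMSE, and the predicted-vs-actual OLS line."""
    yt = np.asarray(getattr(y_true, "conc", y_true), float).ravel()
    yp = np.asarray(getattr(y_pred, "conc", y_pred), float).ravel()
    if yt.size != yp.size:
        raise ValueError("y_true and y_pred lengths differ")
    if yt.size < 2:
        raise ValueError("need at least 2 observations to score")
    sst = float(((yt - yt.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant y_true: R^2 undefined")
    sse = float(((yt - yp) ** 2).sum())
    slope, offset = np.polyfit(yt, yp, 1)
    return Metrics(
        r2=1.0 - sse / sst,
        rmse=float(np.sqrt(sse / yt.size)),
        slope=float(slope),
        offset=float(offset),
    )


def _as_xy(x, y=None):
    x = np.atleast_2d(np.asarray(getattr(x, "intensity", x), dtype=float))
    if y is None:
        return x
    y = np.asarray(getattr(y, "conc", y), dtype=float).ravel()
    if y.size != x.shape[0]:
        raise ValueError("X rows and y length differ")
    return x, y


class PCAScores(TransformerMixin, BaseEstimator):
    """Principal-component scores by SVD of the mean-centered matrix.

    Attributes: ``mean_`` (p,), ``components_`` (k, p) orthonormal rows,
    ``explained_variance_`` (k,) non-increasing, ``explained_variance_ratio_``,
    ``x_scores_`` (n, k) training scores.
    """

    def __init__(self, n_components: int = 11):
        self.n_components = n_components

    def fit(self, X, y=None):
        x = _as_xy(X)
        n, p = x.shape
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if k > min(n - 1, p):
            raise ValueError(
                f"n_components={k} exceeds min(n_samples-1, n_features)={min(n - 1, p)}"
            )
        self.mean_ = x.mean(axis=0)
        xc = x - self.mean_
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        self.components_ = vt[:k]
        self.singular_values_ = s[:k]
        var = s**2 / (n - 1)
        self.explained_variance_ = var[:k]
        total = float(var.sum())
        self.explained_variance_ratio_ = (
            var[:k] / total if total > 0 else np.zeros(k)
        )
        self.x_scores_ = xc @ self.components_.T
        self.n_features_in_ = p
        return self

    def transform(self, X):
        if not hasattr(self, "components_"):
            raise RuntimeError("PCAScores is not fitted")
        x = _as_xy(X)
        if x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {x.shape[1]}"
            )
        return (x - self.mean_) @ self.components_.T


def fit_pca(x, k: int) -> PCAScores:
    return PCAScores(n_components=k).fit(x)


def transform_scores(model, x) -> np.ndarray:
    """Project new samples onto a fitted latent model's components."""
    return model.transform(x)


class PCRRegressor(RegressorMixin, BaseEstimator):
    """Principal component regression: OLS of centered y on PCA scores.

    The score-space coefficients are folded back to the feature space, so
    ``coef_``/``intercept_`` predict directly from spectra.
    """

    kind = "PCR"

    def __init__(self, n_components: int = 11):
        self.n_components = n_components

    def fit(self, X, y):
        x, yv = _as_xy(X, y)
        self.pca_ = PCAScores(n_components=self.n_components).fit(x)
        t = self.pca_.x_scores_
        self.y_mean_ = float(yv.mean())
        gamma, *_ = np.linalg.lstsq(t, yv - self.y_mean_, rcond=None)
        self.coef_ = self.pca_.components_.T @ gamma
        self.intercept_ = self.y_mean_ - float(self.pca_.mean_ @ self.coef_)
        self.x_scores_ = t
        self.explained_variance_ = self.pca_.explained_variance_
        return self

    def transform(self, X):
        return self.pca_.transform(X)

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise RuntimeError("PCRRegressor is not fitted")
        return _as_xy(X) @ self.coef_ + self.intercept_


class PLSRegressorNIPALS(RegressorMixin, BaseEstimator):
    """Univariate-response PLSR fitted by the classical NIPALS recursion.

    Per component: w = X'y / ||X'y||; t = Xw; p = X't / t't; q = y't / t't;
    deflate X by t p' and y by t q.  The feature-space regression vector is
    beta = W (P'W)^-1 q.  For a single response the inner power iteration
    converges in one pass, but the loop is retained with a convergence
    check (tol 1e-10, max 500 iterations per component) for robustness.

    Attributes: ``x_weights_`` W (p, k), ``x_loadings_`` P (p, k),
    ``y_loadings_`` q (k,), ``coef_``, ``intercept_``, ``x_scores_``.
    """

    kind = "PLSR"

    def __init__(self, n_components: int = 11, tol: float = 1e-10, max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x, yv = _as_xy(X, y)
        n, p = x.shape
        k = int(self.n_components)
        if k < 1 or k > min(n - 1, p):
            raise ValueError(
                f"n_components={k} outside [1, min(n_samples-1, n_features)]"
            )
        self.x_mean_ = x.mean(axis=0)
        self.y_mean_ = float(yv.mean())
        xd = x - self.x_mean_
        yd = yv - self.y_mean_
        if np.allclose(yd, 0):
            raise ValueError("zero-variance response: PLSR undefined")
        W = np.zeros((p, k))
        P = np.zeros((p, k))
        q = np.zeros(k)
        T = np.zeros((n, k))
        for a in range(k):
            w = xd.T @ yd
            norm = np.linalg.norm(w)
            if norm < 1e-14:
                raise np.linalg.LinAlgError(
                    f"X'y vanished at component {a + 1}; reduce n_components"
                )
            w /= norm
            for _ in range(self.max_iter):
                t = xd @ w
                tt = float(t @ t)
                qa = float(yd @ t) / tt
                w_new = xd.T @ (yd * qa)
                w_new /= np.linalg.norm(w_new)
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w = w_new
            t = xd @ w
            tt = float(t @ t)
            pa = xd.T @ t / tt
            qa = float(yd @ t) / tt
            xd = xd - np.outer(t, pa)
            yd = yd - t * qa
            W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = T
        self.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        self.coef_ = self.x_rotations_ @ q
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = p
        return self

    def transform(self, X):
        """Out-of-sample PLS scores T = (X - mean) W (P'W)^-1."""
        if not hasattr(self, "x_rotations_"):
            raise RuntimeError("PLSRegressorNIPALS is not fitted")
        x = _as_xy(X)
        if x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {x.shape[1]}"
            )
        return (x - self.x_mean_) @ self.x_rotations_

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise RuntimeError("PLSRegressorNIPALS is not fitted")
        return _as_xy(X) @ self.coef_ + self.intercept_


def fit_pcr(x, y, k: int) -> PCRRegressor:
    return PCRRegressor(n_components=k).fit(x, y)


def fit_plsr(x, y, k: int) -> PLSRegressorNIPALS:
    return PLSRegressorNIPALS(n_components=k).fit(x, y)


# Two CV RMSE values are treated as tied when they differ by less than
# this fraction of sd(y): on noiseless data every k >= the true dimension
# reaches floating-point-level error and the smallest such k should win.
_TIE_REL = 1e-9


def cross_validate_components(
    x,
    y,
    k_grid,
    folds: int = 10,
    seed: int = 0,
    estimator: BaseEstimator | None = None,
    select_by: str = "rmse",
):
    """k-fold CV over a component grid; returns (table, selected k).

    Fold assignment is a seeded shuffle split into ``folds`` contiguous
    chunks; per k, out-of-fold predictions are pooled and scored once.
    Selection minimises pooled CV RMSE (``select_by="rmse"``) or maximises
    pooled CV R^2; near-ties at numerical precision go to the smaller k.
    """
    x, yv = _as_xy(x, y)
    n = x.shape[0]
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in [2, n_samples={n}], got {folds}")
    k_grid = sorted(int(k) for k in k_grid)
    if k_grid[0] < 1:
        raise ValueError("component counts must be >= 1")
    proto = estimator if estimator is not None else PLSRegressorNIPALS()
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    chunks = np.array_split(order, folds)
    min_train = n - max(len(c) for c in chunks)
    if k_grid[-1] > min(min_train - 1, x.shape[1]):
        raise ValueError(
            f"max component count {k_grid[-1]} infeasible in a training fold "
            f"of {min_train} samples"
        )
    rows = []
    scale = float(yv.std()) if yv.std() > 0 else 1.0
    for k in k_grid:
        pred = np.empty(n)
        for test_idx in chunks:
            train_idx = np.setdiff1d(order, test_idx)
            est = clone(proto).set_params(n_components=k)
            est.fit(x[train_idx], yv[train_idx])
            pred[test_idx] = est.predict(x[test_idx])
        m = score_metrics(yv, pred)
        rows.append({"n_components": k, "cv_r2": m.r2, "cv_rmse": m.rmse})
    table = pd.DataFrame(rows)
    if select_by == "rmse":
        best = float(table["cv_rmse"].min())
        ok = table["cv_rmse"] <= best + _TIE_REL * scale
    elif select_by == "r2":
        best = float(table["cv_r2"].max())
        ok = table["cv_r2"] >= best - _TIE_REL
    else:
        raise ValueError("select_by must be 'rmse' or 'r2'")
    selected = int(table.loc[ok, "n_components"].min())
    return table, selected
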