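"""Spectral pretreatments: moving-average smoothing, SNV and MSC.

All three are scikit-learn transformers operating on a sample x
wavelength matrix, plus thin functional wrappers on
:class:`~hydrofuse.containers.SpectraSet`.  A pretreatment chain can be
built from a compact spec string, e.g. ``"ma:11+snv"`` or ``"ma:11+msc"``
(the four chains of a classic NIR pretreatment comparison: raw, smoothing,
smoothing+SNV, smoothing+MSC).

Conventions (documented because instrument-software defaults differ):

* moving average uses a *truncated* (shrinking) window at the edges, so
  the output length equals the input length and no data are fabricated;
* SNV divides by the n-1 (sample) standard deviation;
* the MSC reference spectrum is the column mean of the *fitting* set and
  is reused unchanged for new spectra — it is never refit on test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer

from .containers import SpectraSet

__all__ = [
    "DegenerateSpectrumError",
    "MovingAverage",
    "SNV",
    "MSC",
    "MscReference",
    "moving_average",
    "snv",
    "fit_msc",
    "apply_msc",
    "pipeline_from_spec",
]


class DegenerateSpectrumError(ValueError):
    """A spectrum cannot be pretreated (zero variance or zero scatter slope)."""


def _as_matrix(x) -> np.ndarray:
    x = np.asarray(getattr(x, "intensity", x), dtype=float)
    return np.atleast_2d(x)


def _moving_average_matrix(x: np.ndarray, window: int) -> np.ndarray:
    n = x.shape[1]
    if window % 2 == 0 or not (1 <= window <= n):
        raise ValueError(
            f"window must be odd and within [1, {n}], got {window}"
        )
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def _snv_matrix(x: np.ndarray, sample_ids=None) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() <= 0)
    if bad.size:
        i = int(bad[0])
        name = sample_ids[i] if sample_ids is not None else f"row {i}"
        raise DegenerateSpectrumError(
            f"zero-variance spectrum: sample {name} cannot be SNV-scaled"
        )
    return (x - mean) / sd


def _msc_matrix(x: np.ndarray, ref: np.ndarray, sample_ids=None) -> np.ndarray:
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0:
        raise DegenerateSpectrumError("constant MSC reference spectrum")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    small = np.flatnonzero(np.abs(b) < 1e-12)
    if small.size:
        i = int(small[0])
        name = sample_ids[i] if sample_ids is not None else f"row {i}"
        raise DegenerateSpectrumError(
            f"MSC scatter slope ~ 0 for sample {name}; correction undefined"
        )
    a = x.mean(axis=1) - b * ref.mean()
    return (x - a[:, None]) / b[:, None]


class MovingAverage(TransformerMixin, BaseEstimator):
    """Centered moving-average smoother with truncated edges.

    Parameters
    ----------
    window : int
        Odd window length in points; ``window=1`` is the identity.
    """

    def __init__(self, window: int = 11):
        self.window = window

    def fit(self, X, y=None):
        x = _as_matrix(X)
        _moving_average_matrix(x[:1], self.window)  # validate
        self.n_features_in_ = x.shape[1]
        return self

    def transform(self, X):
        return _moving_average_matrix(_as_matrix(X), self.window)


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: per-spectrum centering and unit scaling."""

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        return _snv_matrix(_as_matrix(X))


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a stored reference.

    ``fit`` records the column-mean reference of the calibration set;
    ``transform`` regresses each spectrum on that reference
    (x = a + b*ref) and returns (x - a)/b.
    """

    def fit(self, X, y=None):
        x = _as_matrix(X)
        if x.shape[0] == 0:
            raise ValueError("cannot fit MSC on an empty set")
        self.reference_ = x.mean(axis=0)
        return self

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise RuntimeError("MSC must be fit before transform")
        return _msc_matrix(_as_matrix(X), self.reference_)


@dataclass(frozen=True)
class MscReference:
    """Stored MSC reference spectrum (mean of a fitting set)."""

    reference_spectrum: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.reference_spectrum, dtype=float).ravel()
        if not np.all(np.isfinite(r)):
            raise ValueError("non-finite reference spectrum")
        object.__setattr__(self, "reference_spectrum", r)


def moving_average(s: SpectraSet, window: int = 11) -> SpectraSet:
    return s.with_intensity(_moving_average_matrix(s.intensity, window))


def snv(s: SpectraSet) -> SpectraSet:
    return s.with_intensity(_snv_matrix(s.intensity, s.sample_ids))


def fit_msc(s: SpectraSet) -> MscReference:
    if s.n_samples == 0:
        raise ValueError("cannot fit MSC on an empty set")
    return MscReference(s.intensity.mean(axis=0))


def apply_msc(s: SpectraSet, ref: MscReference) -> SpectraSet:
    if ref.reference_spectrum.size != s.n_wavelengths:
        raise ValueError("MSC reference length does not match wavelength grid")
    return s.with_intensity(
        _msc_matrix(s.intensity, ref.reference_spectrum, s.sample_ids)
    )


def pipeline_from_spec(spec: str) -> Pipeline:
    """Build a pretreatment pipeline from a spec string.

    Grammar: steps joined by ``+``; ``raw`` (identity), ``ma:<odd window>``,
    ``snv``, ``msc``.  Examples: ``"raw"``, ``"ma:11"``, ``"ma:11+snv"``,
    ``"ma:11+msc"``.
    """
    steps = []
    for i, tok in enumerate(t.strip().lower() for t in spec.split("+")):
        if tok == "raw":
            continue
        if tok == "snv":
            steps.append((f"snv{i}", SNV()))
        elif tok == "msc":
            steps.append((f"msc{i}", MSC()))
        elif tok.startswith("ma:"):
            steps.append((f"ma{i}", MovingAverage(window=int(tok[3:]))))
        else:
            raise ValueError(f"unknown pretreatment token {tok!r} in {spec!r}")
    if not steps:
        steps = [("identity", FunctionTransformer())]
    return Pipeline(steps)
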