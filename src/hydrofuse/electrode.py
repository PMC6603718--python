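"""Cobalt ion-selective electrode calibration (Nikolsky-Eisenman form).

A cobalt electrode immersed in a phosphate solution develops an EMF that
is, over the working range, linear in the logarithm of concentration with
a negative slope:

    EMF_k(c) = e0_k + slope_k * log10(c)          [mV, mV/decade]

Each electrode gets its own ordinary-least-squares calibration line;
inverse prediction maps EMF back to concentration, optionally aggregating
electrodes by geometric mean (the arithmetic mean on the log scale, the
natural average for a log-linear sensor).  Concentration, not activity,
is the regressor — activity-coefficient corrections are out of scope.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import ConcentrationVector, ElectrodeSet

__all__ = [
    "NikolskyCalibrator",
    "fit_nikolsky",
    "predict_conc",
    "two_point_normalize",
]

log = logging.getLogger(__name__)


def _as_emf(emf) -> np.ndarray:
    return np.atleast_2d(np.asarray(getattr(emf, "emf", emf), dtype=float))


def _as_conc(conc) -> np.ndarray:
    return np.asarray(getattr(conc, "conc", conc), dtype=float).ravel()


class NikolskyCalibrator(RegressorMixin, BaseEstimator):
    """Per-electrode log-linear EMF calibration with inverse prediction.

    Parameters
    ----------
    aggregate : {"mean", "per_electrode"}
        ``predict`` returns the geometric mean over electrodes or the full
        per-electrode matrix.

    Attributes
    ----------
    e0_ : ndarray, shape (n_electrodes,)
        Intercepts in mV.
    slope_ : ndarray, shape (n_electrodes,)
        Slopes in mV per decade of concentration (negative for an anion).
    fit_r2_ : ndarray, shape (n_electrodes,)
        Coefficient of determination of each calibration line (EMF space).
    conc_range_ : tuple
        (min, max) calibration concentration; predictions outside it are
        logged as out-of-range, never clipped.
    """

    def __init__(self, aggregate: str = "mean"):
        self.aggregate = aggregate

    def fit(self, emf, conc):
        e = _as_emf(emf)
        c = _as_conc(conc)
        if e.shape[0] != c.size:
            raise ValueError("EMF rows and concentration length differ")
        if c.size < 3:
            raise ValueError("need at least 3 calibration samples")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(c).size < 2:
            raise np.linalg.LinAlgError(
                "need >= 2 distinct concentrations to fit a calibration line"
            )
        logc = np.log10(c)
        design = np.column_stack([np.ones_like(logc), logc])
        coef, *_ = np.linalg.lstsq(design, e, rcond=None)
        self.e0_ = coef[0]
        self.slope_ = coef[1]
        fitted = design @ coef
        sse = ((e - fitted) ** 2).sum(axis=0)
        sst = ((e - e.mean(axis=0)) ** 2).sum(axis=0)
        self.fit_r2_ = 1.0 - sse / sst
        self.conc_range_ = (float(c.min()), float(c.max()))
        self.n_electrodes_ = e.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "slope_"):
            raise RuntimeError("NikolskyCalibrator is not fitted")

    def predict_per_electrode(self, emf) -> np.ndarray:
        """Inverse prediction c_hat = 10**((EMF - e0)/slope), per electrode."""
        self._check_fitted()
        e = _as_emf(emf)
        if e.shape[1] != self.n_electrodes_:
            raise ValueError(
                f"expected {self.n_electrodes_} electrodes, got {e.shape[1]}"
            )
        chat = 10.0 ** ((e - self.e0_[None, :]) / self.slope_[None, :])
        lo, hi = self.conc_range_
        n_out = int(np.sum((chat < lo) | (chat > hi)))
        if n_out:
            log.warning(
                "%d prediction(s) outside calibration range [%.4g, %.4g] mg/L"
                " (not clipped)",
                n_out,
                lo,
                hi,
            )
        return chat

    def predict(self, emf) -> np.ndarray:
        chat = self.predict_per_electrode(emf)
        if self.aggregate == "per_electrode":
            return chat
        if self.aggregate == "mean":
            return np.exp(np.log(chat).mean(axis=1))
        raise ValueError(f"unknown aggregate {self.aggregate!r}")


def fit_nikolsky(emf: ElectrodeSet, conc: ConcentrationVector) -> NikolskyCalibrator:
    """OLS calibration of every electrode's EMF on log10(concentration)."""
    return NikolskyCalibrator().fit(emf, conc)


def predict_conc(
    model: NikolskyCalibrator, emf: ElectrodeSet, aggregate: str = "mean"
) -> ConcentrationVector:
    """Invert a fitted calibration to concentrations (mg/L)."""
    model._check_fitted()
    if aggregate == "per_electrode":
        raise ValueError(
            "per-electrode predictions are a matrix; use model.predict_per_electrode"
        )
    old = model.aggregate
    try:
        model.aggregate = aggregate
        values = model.predict(emf)
    finally:
        model.aggregate = old
    ids = getattr(emf, "sample_ids", None)
    return ConcentrationVector(values, ids)


def two_point_normalize(
    emf: ElectrodeSet,
    ref_low: tuple[float, np.ndarray],
    ref_high: tuple[float, np.ndarray],
) -> ElectrodeSet:
    """Two-point normalization of electrode EMF against known standards.

    ``ref_low``/``ref_high`` are ``(concentration, per-electrode EMF)``
    pairs measured on two standards.  Each electrode's EMF is affinely
    rescaled so its two reference readings land on a shared target line —
    the line through the electrode-mean EMF at the two standards.  This
    compensates inter-electrode offset/sensitivity spread and session
    drift; it is optional (raw data can be used throughout).
    """
    c_lo, e_lo = ref_low
    c_hi, e_hi = ref_high
    if c_lo <= 0 or c_hi <= 0:
        raise ValueError("reference concentrations must be positive")
    if c_lo == c_hi:
        raise ValueError("reference concentrations must be distinct")
    x = _as_emf(emf)
    e_lo = np.broadcast_to(np.asarray(e_lo, float), (x.shape[1],))
    e_hi = np.broadcast_to(np.asarray(e_hi, float), (x.shape[1],))
    if np.any(e_lo == e_hi):
        raise ValueError("an electrode shows identical EMF at both standards")
    t_lo, t_hi = float(e_lo.mean()), float(e_hi.mean())
    alpha = (t_hi - t_lo) / (e_hi - e_lo)
    beta = t_lo - alpha * e_lo
    out = x * alpha[None, :] + beta[None, :]
    ids = getattr(emf, "electrode_ids", None)
    sids = getattr(emf, "sample_ids", None)
    return ElectrodeSet(out, ids, sids)
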