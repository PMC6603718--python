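"""Shared in-memory containers for the three measurement tables.

The toolkit works with three aligned tables: per-sample phosphate
concentrations (mg/L), transmission NIR spectra (intensity over a
wavelength grid in nm) and per-electrode EMF readings (mV).  Each is a
small validated dataclass wrapping numpy arrays; estimators accept either
the container or the bare matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["ConcentrationVector", "SpectraSet", "ElectrodeSet"]


def _make_ids(ids, n: int, prefix: str) -> tuple[str, ...]:
    if ids is None:
        width = max(3, len(str(n)))
        return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))
    ids = tuple(str(s) for s in ids)
    if len(ids) != n:
        raise ValueError(f"expected {n} ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicated sample ids: {dup}")
    return ids


@dataclass(frozen=True)
class ConcentrationVector:
    """Per-sample PO4(3-) concentration in mg/L.

    Concentrations must be finite and strictly positive: the electrode
    model is linear in log10(c) and zero or negative values have no
    meaning for an ion concentration.
    """

    conc: np.ndarray
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        conc = np.asarray(self.conc, dtype=float).ravel()
        if conc.size == 0:
            raise ValueError("empty concentration vector")
        if not np.all(np.isfinite(conc)):
            raise ValueError("non-finite concentration values")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive (mg/L)")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(
            self, "sample_ids", _make_ids(self.sample_ids, conc.size, "S")
        )

    def __len__(self) -> int:
        return self.conc.size


@dataclass(frozen=True)
class SpectraSet:
    """Sample x wavelength intensity matrix with its wavelength axis (nm).

    `intensity` may hold raw detector counts or pretreated values (SNV
    scores, scatter-corrected intensities, absorbance); the axis is always
    strictly ascending wavelengths.
    """

    wavelengths: np.ndarray
    intensity: np.ndarray
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float).ravel()
        x = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending (nm)")
        if x.shape[1] != wl.size:
            raise ValueError(
                f"intensity has {x.shape[1]} columns but {wl.size} wavelengths"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite intensity values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensity", x)
        object.__setattr__(
            self, "sample_ids", _make_ids(self.sample_ids, x.shape[0], "S")
        )

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def with_intensity(self, intensity: np.ndarray) -> "SpectraSet":
        """Same axis and ids, new (pretreated) values."""
        return dataclasses.replace(self, intensity=np.asarray(intensity, float))

    def subset(self, idx) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            self.wavelengths,
            self.intensity[idx],
            tuple(self.sample_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class ElectrodeSet:
    """Sample x electrode EMF matrix in mV."""

    emf: np.ndarray
    electrode_ids: tuple[str, ...] | None = None
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        emf = np.atleast_2d(np.asarray(self.emf, dtype=float))
        if emf.shape[1] < 1:
            raise ValueError("need at least one electrode")
        if not np.all(np.isfinite(emf)):
            raise ValueError("non-finite EMF values")
        object.__setattr__(self, "emf", emf)
        object.__setattr__(
            self, "electrode_ids", _make_ids(self.electrode_ids, emf.shape[1], "E")
        )
        object.__setattr__(
            self, "sample_ids", _make_ids(self.sample_ids, emf.shape[0], "S")
        )

    @property
    def n_samples(self) -> int:
        return self.emf.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.emf.shape[1]

    def subset(self, idx) -> "ElectrodeSet":
        idx = np.asarray(idx)
        return ElectrodeSet(
            self.emf[idx],
            self.electrode_ids,
            tuple(self.sample_ids[i] for i in idx),
        )
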