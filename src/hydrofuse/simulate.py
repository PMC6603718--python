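"""Synthetic phosphate-sensor data generator.

Emulates the two measurement channels of a hydroponic phosphate sensing
study on a paprika-type nutrient solution:

* **Transmission NIR spectra** (904-1700 nm, 128 points) built from a
  Beer-Lambert model: phosphate absorbs in two Gaussian bands centred
  near 945 nm and 1070 nm; the absorbance is overlaid with a water-like
  baseline, broad interfering-ion bands (other nutrient salts absorb in
  overlapping windows), per-spectrum multiplicative/additive scatter and
  detector noise.
* **Cobalt-electrode EMF** following the log-linear (Nikolsky-Eisenman
  form) response: EMF = e0 + slope * log10(c), slope negative and near
  Nernstian, with per-electrode offset and slope variation, a slow linear
  drift in measurement order (electrode-surface ageing over a session)
  and mV-scale noise.

Default noise levels are chosen so that baseline single-channel models
behave like real instruments of this class: a single electrode calibrates
with R^2 roughly 0.6-0.75 and NIR-only PCR/PLSR reaches R^2 roughly
0.4-0.65 over the 10-1300 mg/L design range.  Zero-noise configurations
are exactly invertible by the downstream calibration code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ConcentrationVector, ElectrodeSet, SpectraSet

__all__ = [
    "SpectraSimConfig",
    "EmfSimConfig",
    "design_concentrations",
    "simulate_spectra",
    "simulate_emf",
    "default_wavelength_grid",
]


def default_wavelength_grid() -> np.ndarray:
    """904-1700 nm on 128 points (a common InGaAs mini-spectrometer grid)."""
    return np.linspace(904.0, 1700.0, 128)


def _water_baseline(wl: np.ndarray) -> np.ndarray:
    # flat offset plus the strong water absorption band near 1450 nm
    return 0.15 + 0.5 * np.exp(-0.5 * ((wl - 1450.0) / 70.0) ** 2)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass(frozen=True)
class SpectraSimConfig:
    """Configuration of the Beer-Lambert transmission-spectrum simulator.

    Units: wavelengths in nm, gains in absorbance units per (mg/L),
    scatter/noise in the (dimensionless) intensity scale of ``i0``.
    ``interferent_scales`` set the maximum absorbance amplitude of broad
    co-varying bands from other solutes; they are drawn per sample and cap
    the phosphate information recoverable from the spectra, which scatter
    correction alone cannot restore.  Set them to 0 for a pure
    analyte-plus-scatter model.
    """

    wavelength_grid: np.ndarray = field(default_factory=default_wavelength_grid)
    band_centers: tuple[float, ...] = (945.0, 1070.0)
    band_widths: tuple[float, ...] = (15.0, 30.0)
    band_gains: tuple[float, ...] = (1e-5, 1.5e-5)
    baseline_absorbance: np.ndarray | float | None = None
    interferent_centers: tuple[float, ...] = (950.0, 1080.0, 1000.0)
    interferent_widths: tuple[float, ...] = (18.0, 33.0, 60.0)
    interferent_scales: tuple[float, ...] = (0.01, 0.015, 0.012)
    scatter_mult_sd: float = 0.03
    scatter_add_sd: float = 0.005
    noise_sd: float = 0.005
    i0: float = 1.0
    seed: int = 0

    def __post_init__(self):
        wl = np.asarray(self.wavelength_grid, dtype=float).ravel()
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength_grid must be ascending with >=2 points")
        object.__setattr__(self, "wavelength_grid", wl)
        for name in ("band_centers", "band_widths", "band_gains"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        if not len(self.band_centers) == len(self.band_widths) == len(self.band_gains):
            raise ValueError("band_centers/widths/gains lengths differ")
        for c in self.band_centers:
            if not (wl[0] <= c <= wl[-1]):
                raise ValueError(f"band center {c} nm outside wavelength grid")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be positive")
        if len(self.interferent_centers) != len(self.interferent_widths) or len(
            self.interferent_centers
        ) != len(self.interferent_scales):
            raise ValueError("interferent centers/widths/scales lengths differ")
        if any(v < 0 for v in (self.scatter_mult_sd, self.scatter_add_sd, self.noise_sd)):
            raise ValueError("scatter/noise standard deviations must be >= 0")
        if any(s < 0 for s in self.interferent_scales):
            raise ValueError("interferent scales must be >= 0")
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")

    def baseline(self) -> np.ndarray:
        wl = self.wavelength_grid
        if self.baseline_absorbance is None:
            return _water_baseline(wl)
        b = np.asarray(self.baseline_absorbance, dtype=float)
        if b.ndim == 0:
            return np.full(wl.size, float(b))
        if b.size != wl.size:
            raise ValueError("baseline_absorbance length != wavelength grid length")
        return b.ravel()

    def analyte_absorbance(self, conc: np.ndarray) -> np.ndarray:
        """Noise-free absorbance (baseline + analyte bands), shape (n, p)."""
        wl = self.wavelength_grid
        a = np.tile(self.baseline(), (conc.size, 1))
        for center, width, gain in zip(
            self.band_centers, self.band_widths, self.band_gains
        ):
            a += gain * np.outer(conc, _gauss(wl, center, width))
        return a


@dataclass(frozen=True)
class EmfSimConfig:
    """Configuration of the cobalt-electrode EMF simulator.

    ``e0`` (mV) and ``slope`` (mV per decade of concentration, negative
    for an anion) may be scalars or per-electrode sequences; scalars are
    broadcast with a small deterministic perturbation so electrodes are
    never bit-identical.  ``drift_rate`` is mV per sample index — a proxy
    for the slow change of the electrode oxide layer over a measurement
    session.  ``selectivity`` holds optional (coefficient, interferent
    level) pairs entering inside the logarithm, the full Nikolsky-Eisenman
    form; default none, matching a primary-ion-only calibration.
    """

    n_electrodes: int = 3
    e0: tuple[float, ...] | float = (402.0, 388.0, 415.0)
    slope: tuple[float, ...] | float = (-54.0, -51.0, -58.0)
    drift_rate: tuple[float, ...] | float = 0.3
    noise_sd: float = 10.0
    selectivity: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_electrodes < 1:
            raise ValueError("need at least one electrode")
        for name in ("e0", "slope", "drift_rate"):
            v = getattr(self, name)
            arr = np.broadcast_to(np.asarray(v, dtype=float), (self.n_electrodes,))
            object.__setattr__(self, name, tuple(arr.tolist()))
        if any(s >= 0 for s in self.slope):
            raise ValueError("electrode slopes must be negative (mV/decade)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(
            self,
            "selectivity",
            tuple((float(k), float(a)) for k, a in self.selectivity),
        )


def design_concentrations(
    n: int,
    lo: float = 10.0,
    hi: float = 1300.0,
    scheme: str = "log_uniform",
    seed: int = 0,
) -> ConcentrationVector:
    """Design ``n`` phosphate concentrations in [lo, hi] mg/L.

    Schemes: ``grid`` — levels evenly spaced in log10 including both
    endpoints (a designed dilution series); ``uniform`` — i.i.d. uniform
    on [lo, hi]; ``log_uniform`` — i.i.d. uniform in log10 space, the
    realistic shape for concentrations spanning two decades.
    """
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    if scheme == "grid":
        conc = np.geomspace(lo, hi, n)
    elif scheme == "uniform":
        conc = rng.uniform(lo, hi, n)
    elif scheme == "log_uniform":
        conc = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), n)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return ConcentrationVector(conc)


def simulate_spectra(conc: ConcentrationVector, cfg: SpectraSimConfig) -> SpectraSet:
    """Simulate transmission NIR spectra for the given concentrations.

    Model per sample i at wavelength grid ``wl``::

        A_i = baseline + sum_b gain_b * c_i * G(wl; center_b, width_b)
              + sum_j u_ij * G(wl; icenter_j, iwidth_j)       # interferents
        I_i = (m_i * i0) * 10**(-A_i) + add_i + eps_i

    with u_ij ~ U(0, scale_j), m_i ~ N(1, scatter_mult_sd),
    add_i ~ N(0, scatter_add_sd) and eps pointwise N(0, noise_sd).
    With every random term at zero the map c -> spectrum is deterministic
    and analytically invertible.
    """
    c = conc.conc
    wl = cfg.wavelength_grid
    rng = np.random.default_rng(cfg.seed)
    absorb = cfg.analyte_absorbance(c)
    # draw order is fixed so a given seed is reproducible regardless of
    # which noise terms are switched off
    u = rng.uniform(0.0, 1.0, (c.size, len(cfg.interferent_centers)))
    for j, (center, width, scale) in enumerate(
        zip(cfg.interferent_centers, cfg.interferent_widths, cfg.interferent_scales)
    ):
        if scale > 0:
            absorb += np.outer(scale * u[:, j], _gauss(wl, center, width))
    mult = 1.0 + cfg.scatter_mult_sd * rng.standard_normal(c.size)
    add = cfg.scatter_add_sd * rng.standard_normal(c.size)
    noise = cfg.noise_sd * rng.standard_normal((c.size, wl.size))
    intensity = (mult * cfg.i0)[:, None] * 10.0 ** (-absorb) + add[:, None] + noise
    return SpectraSet(wl, intensity, conc.sample_ids)


def simulate_emf(conc: ConcentrationVector, cfg: EmfSimConfig) -> ElectrodeSet:
    """Simulate per-electrode EMF (mV) for the given concentrations.

    EMF[i, k] = e0_k + slope_k * log10(c_i + sum_j K_j * a_j)
                + drift_rate_k * i + eps,  eps ~ N(0, noise_sd).

    Samples are assumed measured in table order, so the drift term is
    linear in the row index.
    """
    c = conc.conc
    rng = np.random.default_rng(cfg.seed)
    e0 = np.asarray(cfg.e0)
    slope = np.asarray(cfg.slope)
    drift = np.asarray(cfg.drift_rate)
    eff = c + sum(k * a for k, a in cfg.selectivity)
    logc = np.log10(eff)
    idx = np.arange(c.size, dtype=float)
    emf = (
        e0[None, :]
        + np.outer(logc, slope)
        + np.outer(idx, drift)
        + cfg.noise_sd * rng.standard_normal((c.size, cfg.n_electrodes))
    )
    return ElectrodeSet(emf, None, conc.sample_ids)
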