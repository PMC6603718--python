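"""Feature-level fusion of NIR spectra and cobalt-electrode EMF.

Two fusion strategies for predicting phosphate concentration:

* **Concatenation (method A)** — the (optionally pretreated) spectra and
  the raw EMF columns are stacked side by side and fed to PLSR or PCR.
* **PC-NN (method B)** — PCA is fit on the calibration spectra, the
  leading principal-component scores (default 11) are concatenated with
  the EMF columns, and the fused block is fed to the two-hidden-layer
  network of :mod:`hydrofuse.network`.

Because PC scores and mV-scale EMF differ by orders of magnitude, fused
columns are z-standardized by default (``scale=False`` reproduces the
literal unscaled concatenation).  Every statistic involved — pretreatment
references, PCA, column scalers, network scalers — is fit on calibration
rows only; :func:`evaluate_split` enforces this with a leakage guard.

:func:`run_protocol` executes the full comparison grid (pretreatment x
{PLSR, PCR} on spectra alone, per-electrode log-linear calibration, an
EMF-only network, and both fusion methods including the seven network
architecture cases) and returns one consolidated metrics table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .chemometrics import (
    Metrics,
    PCAScores,
    PCRRegressor,
    PLSRegressorNIPALS,
    cross_validate_components,
    score_metrics,
)
from .containers import ConcentrationVector, ElectrodeSet, SpectraSet
from .electrode import NikolskyCalibrator
from .network import NeuralNetRegressor
from .preprocess import pipeline_from_spec
from .simulate import (
    EmfSimConfig,
    SpectraSimConfig,
    design_concentrations,
    simulate_emf,
    simulate_spectra,
)

__all__ = [
    "NETWORK_CASES",
    "LeakageError",
    "FusionDataset",
    "build_fusion",
    "FusionRegressor",
    "evaluate_split",
    "ProtocolConfig",
    "run_protocol",
]

# The seven hidden-layer configurations screened for the fused network:
# (hidden sizes, hidden activations, backprop learning rate).  Case 6 —
# 30 logistic + 25 tanh nodes, rate 0.001 — is the default architecture.
NETWORK_CASES = {
    1: ((30, 25), ("logistic", "tanh"), 0.002),
    2: ((35, 25), ("tanh", "relu"), 0.001),
    3: ((30, 20), ("tanh", "logistic"), 0.003),
    4: ((35, 30), ("logistic", "relu"), 0.001),
    5: ((35, 25), ("relu", "logistic"), 0.002),
    6: ((30, 25), ("logistic", "tanh"), 0.001),
    7: ((25, 20), ("relu", "relu"), 0.003),
}


class LeakageError(RuntimeError):
    """Calibration-only statistics were (or would be) fit on test rows."""


@dataclass(frozen=True)
class FusionDataset:
    """Fused feature block with per-column origin labels."""

    features: np.ndarray
    block_labels: tuple[str, ...]
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        f = np.atleast_2d(np.asarray(self.features, dtype=float))
        labels = tuple(self.block_labels)
        if len(labels) != f.shape[1]:
            raise ValueError("block labels must cover every feature column")
        if any(lb not in ("spectral", "emf") for lb in labels):
            raise ValueError("block labels must be 'spectral' or 'emf'")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "block_labels", labels)


def _spec_matrix(spectra):
    return np.atleast_2d(np.asarray(getattr(spectra, "intensity", spectra), float))


def _emf_matrix(emf):
    if emf is None:
        return None
    return np.atleast_2d(np.asarray(getattr(emf, "emf", emf), float))


def _ids_of(obj):
    return getattr(obj, "sample_ids", None)


def _check_aligned(spectra, emf):
    s_ids, e_ids = _ids_of(spectra), _ids_of(emf)
    if s_ids is not None and e_ids is not None and tuple(s_ids) != tuple(e_ids):
        raise ValueError("spectra and EMF sample ids differ or are re-ordered")


def build_fusion(
    spectra,
    emf,
    method: str = "pc_nn",
    n_pc: int = 11,
    pca: PCAScores | None = None,
) -> FusionDataset:
    """Assemble the fused feature matrix for one of the two methods.

    ``method="pc_nn"`` projects the spectra onto ``n_pc`` principal
    components (fitting the PCA on these rows unless a fitted ``pca``
    from the calibration set is supplied); any other method concatenates
    the full spectral matrix.  ``emf=None`` degrades to a spectra-only
    block.
    """
    _check_aligned(spectra, emf)
    s = _spec_matrix(spectra)
    e = _emf_matrix(emf)
    if e is not None and e.shape[0] != s.shape[0]:
        raise ValueError("spectra and EMF row counts differ")
    if method == "pc_nn":
        if pca is None:
            pca = PCAScores(n_components=n_pc).fit(s)
        block = pca.transform(s)
    else:
        block = s
    labels = ["spectral"] * block.shape[1]
    if e is not None:
        block = np.hstack([block, e])
        labels += ["emf"] * e.shape[1]
    return FusionDataset(block, tuple(labels), _ids_of(spectra))


class FusionRegressor(RegressorMixin, BaseEstimator):
    """Spectra (+) EMF fusion calibrator.

    Parameters
    ----------
    method : {"pc_nn", "plsr_concat", "pcr_concat"}
    n_pc : int
        Principal components kept from the spectra (method B); default 11.
    n_latent : int
        Latent components of the PLSR/PCR head (method A).
    preprocessing : str or None
        Pretreatment spec for the spectral block (``"ma:11+snv"`` etc.);
        default None = raw spectra, the configuration used for fusion.
    scale : bool
        z-standardize fused columns (calibration statistics only).
    hidden_layer_sizes, activations, algorithm, learning_rate, max_epochs,
    random_state : network settings for ``method="pc_nn"``.
    """

    def __init__(
        self,
        method: str = "pc_nn",
        n_pc: int = 11,
        n_latent: int = 11,
        preprocessing: str | None = None,
        scale: bool = True,
        hidden_layer_sizes=(30, 25),
        activations=("logistic", "tanh"),
        algorithm: str = "lm",
        learning_rate: float = 0.001,
        max_epochs: int = 300,
        random_state=None,
    ):
        self.method = method
        self.n_pc = n_pc
        self.n_latent = n_latent
        self.preprocessing = preprocessing
        self.scale = scale
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activations = activations
        self.algorithm = algorithm
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.random_state = random_state

    def _features(self, spectra, emf, fit: bool) -> np.ndarray:
        _check_aligned(spectra, emf)
        s = _spec_matrix(spectra)
        e = _emf_matrix(emf)
        if not fit and (e is None) != (self.n_emf_ == 0):
            raise ValueError("EMF block presence differs from the fitted model")
        if self.preprocessing:
            if fit:
                self.preprocess_ = pipeline_from_spec(self.preprocessing)
                s = self.preprocess_.fit_transform(s)
            else:
                s = self.preprocess_.transform(s)
        if self.method == "pc_nn":
            if fit:
                self.pca_ = PCAScores(n_components=self.n_pc).fit(s)
            block = self.pca_.transform(s)
        elif self.method in ("plsr_concat", "pcr_concat"):
            block = s
        else:
            raise ValueError(f"unknown fusion method {self.method!r}")
        if e is not None:
            block = np.hstack([block, e])
        if fit:
            self.n_emf_ = 0 if e is None else e.shape[1]
            self.block_labels_ = tuple(
                ["spectral"] * (block.shape[1] - self.n_emf_)
                + ["emf"] * self.n_emf_
            )
            if self.scale:
                self.scale_mean_ = block.mean(axis=0)
                sd = block.std(axis=0)
                self.scale_sd_ = np.where(sd > 0, sd, 1.0)
        if self.scale:
            block = (block - self.scale_mean_) / self.scale_sd_
        return block

    def fit(self, spectra, emf, y, sample_ids=None):
        yv = np.asarray(getattr(y, "conc", y), dtype=float).ravel()
        ids = sample_ids if sample_ids is not None else _ids_of(spectra)
        self.fit_sample_ids_ = None if ids is None else tuple(ids)
        f = self._features(spectra, emf, fit=True)
        if f.shape[0] != yv.size:
            raise ValueError("feature rows and y length differ")
        if self.method == "plsr_concat":
            k = min(self.n_latent, f.shape[0] - 1, f.shape[1])
            self.model_ = PLSRegressorNIPALS(n_components=k).fit(f, yv)
        elif self.method == "pcr_concat":
            k = min(self.n_latent, f.shape[0] - 1, f.shape[1])
            self.model_ = PCRRegressor(n_components=k).fit(f, yv)
        else:
            self.model_ = NeuralNetRegressor(
                hidden_layer_sizes=self.hidden_layer_sizes,
                activations=self.activations,
                algorithm=self.algorithm,
                learning_rate=self.learning_rate,
                max_epochs=self.max_epochs,
                random_state=self.random_state,
            ).fit(f, yv)
        return self

    def predict(self, spectra, emf=None):
        if not hasattr(self, "model_"):
            raise RuntimeError("FusionRegressor is not fitted")
        f = self._features(spectra, emf, fit=False)
        return self.model_.predict(f)


def _metrics_pair(model, calib, test) -> dict[str, Metrics]:
    sp_c, emf_c, y_c = calib
    sp_t, emf_t, y_t = test
    return {
        "calibration": score_metrics(y_c, model.predict(sp_c, emf_c)),
        "test": score_metrics(y_t, model.predict(sp_t, emf_t)),
    }


def evaluate_split(model: FusionRegressor, calib, test) -> dict[str, Metrics]:
    """Fit (if needed) on the calibration triple and score both splits.

    ``calib``/``test`` are ``(spectra, emf_or_None, y)`` triples.  The
    leakage guard refuses to score when rows used to fit calibration
    statistics overlap the test ids — unless the two sets are *identical*,
    which is read as a deliberate resubstitution check.
    """
    sp_c, emf_c, y_c = calib
    sp_t, _, _ = test
    if not hasattr(model, "model_"):
        model.fit(sp_c, emf_c, y_c)
    fit_ids = getattr(model, "fit_sample_ids_", None)
    test_ids = _ids_of(sp_t)
    if fit_ids is not None and test_ids is not None:
        overlap = set(fit_ids) & set(test_ids)
        identical = set(fit_ids) == set(test_ids)
        if overlap and not identical:
            raise LeakageError(
                f"{len(overlap)} test sample(s) were used to fit calibration "
                f"statistics (e.g. {sorted(overlap)[:3]})"
            )
    return _metrics_pair(model, calib, test)


# ---------------------------------------------------------------------------
# full comparison protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolConfig:
    """One self-contained run of the full model-comparison grid.

    ``spectra_overrides``/``emf_overrides`` patch individual simulator
    fields (the seeds are always derived from ``seed``).  ``net_max_epochs``
    bounds the LM iterations of each network fit in the grid.
    """

    seed: int = 0
    n_samples: int = 80
    n_calib: int = 56
    n_test: int = 24
    lo: float = 10.0
    hi: float = 1300.0
    scheme: str = "log_uniform"
    split_strategy: str = "rank_stratified"
    n_pc: int = 11
    n_latent: int = 11
    nir_k_grid: tuple[int, ...] = tuple(range(1, 16))
    nir_cv_folds: int = 10
    include_emf: bool = True
    network_cases: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    emf_ann_hidden: tuple[int, int] = (12, 10)
    emf_ann_activations: tuple[str, str] = ("tanh", "logistic")
    net_max_epochs: int = 5
    preprocessings: tuple[str, ...] = ("raw", "ma:11", "ma:11+snv", "ma:11+msc")
    spectra_overrides: dict = field(default_factory=dict)
    emf_overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _row(stage, prep, model, k, cal: Metrics, test: Metrics) -> dict:
    return {
        "stage": stage,
        "preprocessing": prep,
        "model": model,
        "n_components": k,
        "r2_calibration": cal.r2,
        "rmse_calibration_mg_per_l": cal.rmse,
        "r2_test": test.r2,
        "rmse_test_mg_per_l": test.rmse,
        "slope_test": test.slope,
        "offset_test": test.offset,
    }


def run_protocol(config: ProtocolConfig | None = None, **overrides):
    """Run the end-to-end comparison grid on simulated data.

    Returns ``(report, artifacts)``: a 21-row metrics table (8 spectra-only
    pretreatment x model rows, 3 per-electrode rows, 1 EMF-network row,
    2 concatenation-fusion rows, 7 PC-NN architecture rows when all
    stages are enabled) and a dict with the generated data, split and
    fitted models.  Fully deterministic under ``config.seed``.
    """
    from .io import split_samples  # local import to avoid a cycle

    if config is None:
        config = ProtocolConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")

    seeds = _derived_seeds(config.seed, 12 + len(config.network_cases))
    conc = design_concentrations(
        config.n_samples, config.lo, config.hi, config.scheme, seeds[0]
    )
    spectra = simulate_spectra(
        conc, SpectraSimConfig(seed=seeds[1], **config.spectra_overrides)
    )
    emf = (
        simulate_emf(conc, EmfSimConfig(seed=seeds[2], **config.emf_overrides))
        if config.include_emf
        else None
    )
    calib_ids, test_ids = split_samples(
        conc.sample_ids,
        config.n_calib,
        config.n_test,
        strategy=config.split_strategy,
        seed=seeds[3],
        conc=conc.conc,
    )
    pos = {sid: i for i, sid in enumerate(conc.sample_ids)}
    ci = np.array([pos[s] for s in calib_ids])
    ti = np.array([pos[s] for s in test_ids])
    sp_c, sp_t = spectra.subset(ci), spectra.subset(ti)
    y_c = ConcentrationVector(conc.conc[ci], calib_ids)
    y_t = ConcentrationVector(conc.conc[ti], test_ids)
    emf_c = emf.subset(ci) if emf is not None else None
    emf_t = emf.subset(ti) if emf is not None else None

    rows = []
    models = {}

    # --- spectra-only pretreatment x {PLSR, PCR} grid ---
    # component counts follow the study procedure: 10-fold CV on the
    # calibration set, per pretreatment and model
    for prep in config.preprocessings:
        for name, cls in (("PLSR", PLSRegressorNIPALS), ("PCR", PCRRegressor)):
            pipe = pipeline_from_spec(prep)
            xc = pipe.fit_transform(sp_c.intensity)
            xt = pipe.transform(sp_t.intensity)
            _, k = cross_validate_components(
                xc,
                y_c.conc,
                config.nir_k_grid,
                folds=config.nir_cv_folds,
                seed=seeds[-1],
                estimator=cls(),
            )
            est = cls(n_components=k).fit(xc, y_c.conc)
            cal = score_metrics(y_c.conc, est.predict(xc))
            tst = score_metrics(y_t.conc, est.predict(xt))
            rows.append(_row("nir", prep, name, k, cal, tst))
            models[f"nir/{prep}/{name}"] = est

    if emf is not None:
        # --- per-electrode log-linear calibration ---
        cal_model = NikolskyCalibrator().fit(emf_c, y_c.conc)
        chat_c = cal_model.predict_per_electrode(emf_c)
        chat_t = cal_model.predict_per_electrode(emf_t)
        for j, eid in enumerate(emf.electrode_ids):
            cal = score_metrics(y_c.conc, chat_c[:, j])
            tst = score_metrics(y_t.conc, chat_t[:, j])
            rows.append(_row("emf", "-", f"nikolsky[{eid}]", 1, cal, tst))
        models["emf/nikolsky"] = cal_model

        # --- EMF-only network ---
        ann = NeuralNetRegressor(
            hidden_layer_sizes=config.emf_ann_hidden,
            activations=config.emf_ann_activations,
            algorithm="lm",
            max_epochs=config.net_max_epochs,
            random_state=seeds[4],
        ).fit(emf_c.emf, y_c.conc)
        cal = score_metrics(y_c.conc, ann.predict(emf_c.emf))
        tst = score_metrics(y_t.conc, ann.predict(emf_t.emf))
        h1, h2 = config.emf_ann_hidden
        rows.append(_row("emf", "-", f"ann[{h1}x{h2}]", 0, cal, tst))
        models["emf/ann"] = ann

        # --- method A: raw concatenation into PLSR / PCR ---
        for method in ("plsr_concat", "pcr_concat"):
            fm = FusionRegressor(
                method=method, n_latent=config.n_latent, random_state=seeds[5]
            )
            res = evaluate_split(fm, (sp_c, emf_c, y_c), (sp_t, emf_t, y_t))
            rows.append(
                _row(
                    "fusion_concat",
                    "raw",
                    method,
                    fm.model_.n_components,
                    res["calibration"],
                    res["test"],
                )
            )
            models[f"fusion/{method}"] = fm

        # --- method B: PC scores + EMF into the network, 7 cases ---
        for i, case in enumerate(config.network_cases):
            hidden, acts, lr = NETWORK_CASES[case]
            fm = FusionRegressor(
                method="pc_nn",
                n_pc=config.n_pc,
                hidden_layer_sizes=hidden,
                activations=acts,
                learning_rate=lr,
                max_epochs=config.net_max_epochs,
                random_state=seeds[6 + i],
            )
            res = evaluate_split(fm, (sp_c, emf_c, y_c), (sp_t, emf_t, y_t))
            rows.append(
                _row(
                    "fusion_pcnn",
                    "raw",
                    f"pc_nn[case{case}]",
                    config.n_pc,
                    res["calibration"],
                    res["test"],
                )
            )
            models[f"fusion/pc_nn_case{case}"] = fm

    report = pd.DataFrame(rows)
    report.insert(0, "seed", config.seed)
    report.insert(1, "config_hash", config.config_hash())
    artifacts = {
        "config": config,
        "conc": conc,
        "spectra": spectra,
        "emf": emf,
        "calib_ids": calib_ids,
        "test_ids": test_ids,
        "models": models,
    }
    return report, artifacts
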