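"""CSV readers/writers, sample splitting and model (de)serialization.

Formats (comma-separated, UTF-8, one header row):

* spectra CSV — column 0 ``sample_id``, remaining headers the wavelengths
  in nm (strictly ascending), cells the intensity values;
* EMF CSV — column 0 ``sample_id``, remaining headers electrode ids,
  cells in mV;
* concentration CSV — columns ``sample_id, po4_mg_per_l``.

Models serialize to JSON with arrays as nested lists; the registry covers
the electrode calibrator, both latent models, the network and the fusion
model (including its stored pretreatment state), so any fitted model can
be saved and replayed on new data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import PCAScores, PCRRegressor, PLSRegressorNIPALS
from .containers import ConcentrationVector, ElectrodeSet, SpectraSet
from .electrode import NikolskyCalibrator
from .fusion import FusionRegressor
from .network import NeuralNetRegressor
from .preprocess import MSC, pipeline_from_spec

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_emf_csv",
    "write_emf_csv",
    "read_conc_csv",
    "write_conc_csv",
    "split_samples",
    "write_report",
    "save_model",
    "load_model",
]


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    ids = df["sample_id"].tolist()
    dup = sorted({s for s in ids if ids.count(s) > 1})
    if dup:
        raise ValueError(f"{path}: duplicated sample ids {dup}")
    body = df.drop(columns="sample_id")
    for col in body.columns:
        vals = pd.to_numeric(body[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}"
            )
        body[col] = vals
    body.index = ids
    return body


def read_spectra_csv(path) -> SpectraSet:
    body = _read_table(path)
    try:
        wl = np.array([float(c) for c in body.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: wavelength headers must be numeric") from exc
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path}: wavelength header not strictly ascending")
    return SpectraSet(wl, body.to_numpy(), tuple(body.index))


def write_spectra_csv(s: SpectraSet, path) -> None:
    df = pd.DataFrame(
        s.intensity, index=list(s.sample_ids), columns=[f"{w:g}" for w in s.wavelengths]
    )
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g")


def read_emf_csv(path) -> ElectrodeSet:
    body = _read_table(path)
    return ElectrodeSet(body.to_numpy(), tuple(body.columns), tuple(body.index))


def write_emf_csv(e: ElectrodeSet, path) -> None:
    df = pd.DataFrame(
        e.emf, index=list(e.sample_ids), columns=list(e.electrode_ids)
    )
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g")


def read_conc_csv(path) -> ConcentrationVector:
    body = _read_table(path)
    if "po4_mg_per_l" not in body.columns:
        raise ValueError(f"{path}: missing 'po4_mg_per_l' column")
    return ConcentrationVector(body["po4_mg_per_l"].to_numpy(), tuple(body.index))


def write_conc_csv(c: ConcentrationVector, path) -> None:
    df = pd.DataFrame(
        {"po4_mg_per_l": c.conc}, index=list(c.sample_ids)
    )
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g")


def write_report(report: pd.DataFrame, path) -> None:
    """Write a metrics report with a fixed float format (reproducible bytes)."""
    report.to_csv(path, index=False, float_format="%.10g")


def split_samples(
    ids,
    n_calib: int,
    n_test: int,
    strategy: str = "rank_stratified",
    seed: int = 0,
    conc=None,
):
    """Split sample ids into disjoint calibration and test sets.

    ``random`` permutes; ``rank_stratified`` orders samples by
    concentration, divides the order into ``n_test`` contiguous blocks and
    draws one test sample per block, so both sets span the full
    concentration range.  Deterministic per seed.
    """
    ids = list(ids)
    n = len(ids)
    if n_calib < 0 or n_test < 0 or n_calib + n_test > n:
        raise ValueError(
            f"split sizes {n_calib}+{n_test} exceed available {n} samples"
        )
    rng = np.random.default_rng(seed)
    if n_test == 0:
        order = rng.permutation(n)
        calib = [ids[i] for i in sorted(order[:n_calib])]
        return tuple(calib), ()
    if strategy == "random":
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
        pool = [i for i in order[n_test:]]
        calib_idx = sorted(pool[:n_calib])
        test_idx = sorted(test_idx)
    elif strategy == "rank_stratified":
        if conc is None:
            raise ValueError("rank_stratified split needs the concentration vector")
        conc = np.asarray(getattr(conc, "conc", conc), float).ravel()
        if conc.size != n:
            raise ValueError("concentration length does not match ids")
        ranked = np.argsort(conc, kind="stable")
        blocks = np.array_split(ranked, n_test)
        test_idx = sorted(int(rng.choice(b)) for b in blocks)
        pool = [int(i) for i in ranked if int(i) not in set(test_idx)]
        pool = rng.permutation(pool).tolist()
        calib_idx = sorted(pool[:n_calib])
    else:
        raise ValueError(f"unknown split strategy {strategy!r}")
    return (
        tuple(ids[i] for i in calib_idx),
        tuple(ids[i] for i in test_idx),
    )


# ---------------------------------------------------------------------------
# model JSON serialization
# ---------------------------------------------------------------------------


def _arr(a):
    return np.asarray(a).tolist()


def _model_state(model) -> dict:
    if isinstance(model, NikolskyCalibrator):
        return {
            "class": "NikolskyCalibrator",
            "params": model.get_params(),
            "state": {
                "e0_": _arr(model.e0_),
                "slope_": _arr(model.slope_),
                "fit_r2_": _arr(model.fit_r2_),
                "conc_range_": list(model.conc_range_),
                "n_electrodes_": model.n_electrodes_,
            },
        }
    if isinstance(model, PCAScores):
        return {
            "class": "PCAScores",
            "params": model.get_params(),
            "state": {
                "mean_": _arr(model.mean_),
                "components_": _arr(model.components_),
                "singular_values_": _arr(model.singular_values_),
                "explained_variance_": _arr(model.explained_variance_),
                "explained_variance_ratio_": _arr(model.explained_variance_ratio_),
                "n_features_in_": model.n_features_in_,
            },
        }
    if isinstance(model, PCRRegressor):
        return {
            "class": "PCRRegressor",
            "params": model.get_params(),
            "state": {
                "pca": _model_state(model.pca_),
                "y_mean_": model.y_mean_,
                "coef_": _arr(model.coef_),
                "intercept_": model.intercept_,
            },
        }
    if isinstance(model, PLSRegressorNIPALS):
        return {
            "class": "PLSRegressorNIPALS",
            "params": model.get_params(),
            "state": {
                "x_mean_": _arr(model.x_mean_),
                "y_mean_": model.y_mean_,
                "x_weights_": _arr(model.x_weights_),
                "x_loadings_": _arr(model.x_loadings_),
                "y_loadings_": _arr(model.y_loadings_),
                "x_rotations_": _arr(model.x_rotations_),
                "coef_": _arr(model.coef_),
                "intercept_": model.intercept_,
                "n_features_in_": model.n_features_in_,
            },
        }
    if isinstance(model, NeuralNetRegressor):
        return {
            "class": "NeuralNetRegressor",
            "params": model.get_params(),
            "state": {
                "weights_": [_arr(w) for w in model.weights_],
                "biases_": [_arr(b) for b in model.biases_],
                "layer_sizes_": list(model.layer_sizes_),
                "x_mean_": _arr(model.x_mean_),
                "x_scale_": _arr(model.x_scale_),
                "y_mean_": model.y_mean_,
                "y_scale_": model.y_scale_,
                "loss_trace_": [float(v) for v in model.loss_trace_],
            },
        }
    if isinstance(model, FusionRegressor):
        state = {
            "model": _model_state(model.model_),
            "n_emf_": model.n_emf_,
            "block_labels_": list(model.block_labels_),
            "fit_sample_ids_": (
                None if model.fit_sample_ids_ is None else list(model.fit_sample_ids_)
            ),
        }
        if model.scale:
            state["scale_mean_"] = _arr(model.scale_mean_)
            state["scale_sd_"] = _arr(model.scale_sd_)
        if getattr(model, "pca_", None) is not None and model.method == "pc_nn":
            state["pca"] = _model_state(model.pca_)
        if model.preprocessing:
            state["msc_references"] = [
                _arr(step.reference_)
                for _, step in model.preprocess_.steps
                if isinstance(step, MSC)
            ]
        return {
            "class": "FusionRegressor",
            "params": model.get_params(),
            "state": state,
        }
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


_CLASSES = {
    "NikolskyCalibrator": NikolskyCalibrator,
    "PCAScores": PCAScores,
    "PCRRegressor": PCRRegressor,
    "PLSRegressorNIPALS": PLSRegressorNIPALS,
    "NeuralNetRegressor": NeuralNetRegressor,
    "FusionRegressor": FusionRegressor,
}


def _restore(doc: dict):
    cls = _CLASSES[doc["class"]]
    model = cls(**doc["params"])
    st = doc["state"]
    if doc["class"] == "NikolskyCalibrator":
        model.e0_ = np.array(st["e0_"])
        model.slope_ = np.array(st["slope_"])
        model.fit_r2_ = np.array(st["fit_r2_"])
        model.conc_range_ = tuple(st["conc_range_"])
        model.n_electrodes_ = int(st["n_electrodes_"])
    elif doc["class"] == "PCAScores":
        for k in (
            "mean_",
            "components_",
            "singular_values_",
            "explained_variance_",
            "explained_variance_ratio_",
        ):
            setattr(model, k, np.array(st[k]))
        model.n_features_in_ = int(st["n_features_in_"])
    elif doc["class"] == "PCRRegressor":
        model.pca_ = _restore(st["pca"])
        model.y_mean_ = float(st["y_mean_"])
        model.coef_ = np.array(st["coef_"])
        model.intercept_ = float(st["intercept_"])
    elif doc["class"] == "PLSRegressorNIPALS":
        for k in ("x_mean_", "x_weights_", "x_loadings_", "y_loadings_",
                  "x_rotations_", "coef_"):
            setattr(model, k, np.array(st[k]))
        model.y_mean_ = float(st["y_mean_"])
        model.intercept_ = float(st["intercept_"])
        model.n_features_in_ = int(st["n_features_in_"])
    elif doc["class"] == "NeuralNetRegressor":
        model.weights_ = [np.array(w) for w in st["weights_"]]
        model.biases_ = [np.array(b) for b in st["biases_"]]
        model.layer_sizes_ = tuple(st["layer_sizes_"])
        model.x_mean_ = np.array(st["x_mean_"])
        model.x_scale_ = np.array(st["x_scale_"])
        model.y_mean_ = float(st["y_mean_"])
        model.y_scale_ = float(st["y_scale_"])
        model.loss_trace_ = list(st["loss_trace_"])
    elif doc["class"] == "FusionRegressor":
        model.model_ = _restore(st["model"])
        model.n_emf_ = int(st["n_emf_"])
        model.block_labels_ = tuple(st["block_labels_"])
        ids = st.get("fit_sample_ids_")
        model.fit_sample_ids_ = None if ids is None else tuple(ids)
        if model.scale:
            model.scale_mean_ = np.array(st["scale_mean_"])
            model.scale_sd_ = np.array(st["scale_sd_"])
        if "pca" in st:
            model.pca_ = _restore(st["pca"])
        if model.preprocessing:
            model.preprocess_ = pipeline_from_spec(model.preprocessing)
            refs = iter(st.get("msc_references", []))
            for _, step in model.preprocess_.steps:
                if isinstance(step, MSC):
                    step.reference_ = np.array(next(refs))
    return model


def save_model(model, path) -> None:
    """Serialize a fitted model to JSON."""
    Path(path).write_text(json.dumps(_model_state(model), indent=1))


def load_model(path):
    """Restore a model saved by :func:`save_model`."""
    return _restore(json.loads(Path(path).read_text()))
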