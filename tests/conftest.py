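import numpy as np
import pytest

import hydrofuse as hf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free concentrations + spectra + EMF, exactly invertible."""
    conc = hf.design_concentrations(40, 10, 1300, "grid", seed=0)
    scfg = hf.SpectraSimConfig(
        interferent_scales=(0.0, 0.0, 0.0),
        scatter_mult_sd=0.0,
        scatter_add_sd=0.0,
        noise_sd=0.0,
        seed=0,
    )
    ecfg = hf.EmfSimConfig(
        e0=400.0, slope=-55.0, drift_rate=0.0, noise_sd=0.0, seed=0
    )
    return conc, hf.simulate_spectra(conc, scfg), hf.simulate_emf(conc, ecfg)


@pytest.fixture(scope="session")
def midnoise_dataset():
    """80 samples under the default (study-condition) noise regime."""
    conc = hf.design_concentrations(80, 10, 1300, "log_uniform", seed=5)
    spectra = hf.simulate_spectra(conc, hf.SpectraSimConfig(seed=6))
    emf = hf.simulate_emf(conc, hf.EmfSimConfig(seed=7))
    return conc, spectra, emf


def split_indices(conc, n_calib=56, n_test=24, seed=0):
    from hydrofuse.io import split_samples

    calib_ids, test_ids = split_samples(
        conc.sample_ids, n_calib, n_test, "rank_stratified", seed, conc.conc
    )
    pos = {s: i for i, s in enumerate(conc.sample_ids)}
    return (
        np.array([pos[s] for s in calib_ids]),
        np.array([pos[s] for s in test_ids]),
    )
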