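import warnings

import numpy as np
import pytest

from patchsmlm import (
    NoiseParams,
    OpticalConfig,
    PSFStats,
    SimulationConfig,
    simulate_video,
)


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def default_noise():
    return NoiseParams()


@pytest.fixture(scope="session")
def default_optics():
    return OpticalConfig()


@pytest.fixture(scope="session")
def known_psf():
    """PSFStats matching the simulator's default width, bypassing the fitter."""
    return PSFStats(sigma_mean=0.5, sigma_std=0.0, amp_mean=1.0, amp_std=0.0, n_fits=1)


@pytest.fixture(scope="session")
def sparse_video():
    """Low-density, high-SNR stack with ground truth (easy regime)."""
    cfg = SimulationConfig(n_frames=40, density_um2=0.1, snr=8.0)
    return simulate_video(cfg, seed=5)


def noiseless_config(**kw):
    base = dict(
        snr=None,
        mean_photons=1000.0,
        photon_cv=0.0,
        noise=NoiseParams(background_photons=0.0, gauss_mean=0.0, gauss_std=0.0, poisson_enabled=False),
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
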