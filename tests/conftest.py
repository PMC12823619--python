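import numpy as np
import pytest

from senometrix.containers import CellLabelMask, Spectrum, SpectrumSet
from senometrix.synthetic import SpectraSimConfig, TpefSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def noiseless_tpef_cfg():
    """Artifact-free punctate field used as a clean oracle fixture."""
    return TpefSimConfig(
        image_size=(160, 160), n_cells=3, background_sd=0.0,
        n_outliers=0, serpentine_shift=0, seed=7,
    )


@pytest.fixture
def quiet_spectra_cfg():
    """Deterministic spectra: no peak noise, no TIC jitter."""
    return SpectraSimConfig(noise_cv=0.0, tic_jitter=1.0,
                            n_spectra_per_group=3, seed=3)


@pytest.fixture
def square_cell_mask():
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[5:15, 5:15] = 1
    return CellLabelMask(labels)


@pytest.fixture
def gaussian_spectrum():
    """Factory for spectra made of Gaussian peaks on a regular m/z grid."""

    def make(centers, amps, fwhm=0.5, mz_start=600.0, mz_stop=1500.0,
             step=0.05, **ids):
        mz = np.arange(mz_start, mz_stop + step / 2, step)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        intensity = np.zeros_like(mz)
        for c, a in zip(centers, amps):
            intensity += a * np.exp(-((mz - c) ** 2) / (2 * sigma**2))
        return Spectrum(mz=mz, intensity=intensity, **ids)

    return make
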