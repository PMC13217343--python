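import numpy as np
import pytest

from kinfit import (
    GaussianBand,
    IRFParameters,
    KineticParameters,
    KineticScheme,
    NoiseSpec,
    SpectrumSpec,
    generate_dataset,
)
from kinfit.synthetic import default_time_grid


@pytest.fixture
def parallel2():
    return KineticScheme.parallel(2)


@pytest.fixture
def sequential2():
    return KineticScheme.sequential(2)


@pytest.fixture
def narrow_irf():
    return IRFParameters(t0=0.0, fwhm=0.1)


@pytest.fixture
def biexp_params(narrow_irf):
    return KineticParameters((1.5, 4.6), narrow_irf)


@pytest.fixture
def two_band_spec():
    return SpectrumSpec(
        bands=(
            (GaussianBand(1.0, 450.0, 40.0),),
            (GaussianBand(0.8, 550.0, 50.0),),
        )
    )


@pytest.fixture
def small_dataset(parallel2, biexp_params, two_band_spec):
    """Noiseless 30-wavelength x 50-time two-species dataset."""
    wl = np.linspace(400.0, 620.0, 30)
    t = default_time_grid(t_max=25.0, fwhm=0.1, n=50)
    data, truth = generate_dataset(
        parallel2, biexp_params, two_band_spec, wl, t, NoiseSpec("sigma", 0.0)
    )
    return data, truth


@pytest.fixture
def noisy_dataset(parallel2, biexp_params, two_band_spec):
    """Same recipe with noise at SNR 100."""
    wl = np.linspace(400.0, 620.0, 30)
    t = default_time_grid(t_max=25.0, fwhm=0.1, n=50)
    data, truth = generate_dataset(
        parallel2,
        biexp_params,
        two_band_spec,
        wl,
        t,
        NoiseSpec("target_snr", 100.0, rng_seed=7),
    )
    return data, truth
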