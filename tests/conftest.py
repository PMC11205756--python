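import numpy as np
import pytest

from algadens import SpectrumGeneratorConfig, load_table3, synth_dilution_series


@pytest.fixture(scope="session")
def table3():
    """The packaged ten-dilution reference series."""
    return load_table3()


@pytest.fixture(scope="session")
def noiseless_set():
    """Noise-free synthetic dilution series with paired spectra."""
    return synth_dilution_series(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def flat_cfg():
    """Generator with flat spectral profiles: A_max = 3.29, k = 0.0022 everywhere."""
    return SpectrumGeneratorConfig(
        peaks=(), amax_baseline=3.29, amax_scale=0.0,
        k_baseline=0.0022, k_scale=0.0,
    )
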