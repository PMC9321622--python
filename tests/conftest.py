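import numpy as np
import pytest

from specbind.synthetic import GroundTruth, gen_titration


@pytest.fixture
def truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture
def noiseless_series(truth):
    """Noiseless titrations at the three study temperatures."""
    return gen_titration(truth)


@pytest.fixture
def gaussian_emission():
    """Gaussian emission band centred at 327 nm on a 220-500 nm grid."""
    from specbind.spectra import Spectrum

    grid = np.arange(220.0, 500.0 + 1e-9, 1.0)
    signal = 1000.0 * np.exp(-((grid - 327.0) ** 2) / (2 * 18.0**2))
    return Spectrum(grid, signal, "emission", label="gaussian 327")
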