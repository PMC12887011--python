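import numpy as np
import pytest

from kedgect.spectrum import Spectrum, make_spectrum
from kedgect.sweep import SweepConfig, run_sweep


@pytest.fixture(scope="session")
def spectrum_1e5():
    return make_spectrum(N0=1e5)


@pytest.fixture(scope="session")
def noise_free_sweep():
    """Noise-free threshold sweep of the study phantom, reduced geometry."""
    return run_sweep(SweepConfig(preset="reduced", noise_free=True, seed=0))


@pytest.fixture(scope="session")
def noisy_sweep():
    """Seeded noisy sweep (4 averaged realizations) with separability."""
    return run_sweep(SweepConfig(preset="reduced", noise_free=False,
                                 n_realizations=4, seed=1))


def mono_spectrum(energy_keV: float, n0: float = 1e6) -> Spectrum:
    """Single-line test spectrum: all photons in the 1 keV bin at energy."""
    edges = np.arange(20.0, 120.0)
    fl = np.zeros_like(edges)
    fl[int(energy_keV - 20.0)] = n0
    return Spectrum(edges, fl, 120.0)
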