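"""Shared fixtures: hand-built spectra and session-scoped synthetic libraries."""

import numpy as np
import pytest

from specdenoise import SynthConfig, generate_library, make_spectrum


@pytest.fixture()
def simple_spectrum():
    return make_spectrum(
        [100.0, 150.0, 200.0, 250.0],
        [10.0, 100.0, 40.0, 5.0],
        id="simple",
        precursor_mz=300.0,
    )


@pytest.fixture(scope="session")
def default_library():
    """The 200-spectrum benchmark: 50 compounds x 4 replicate scans, seed 42."""
    return generate_library(SynthConfig.default(seed=42))


@pytest.fixture(scope="session")
def network_library():
    """One reference spectrum per compound, collapse-prone regime, seed 42."""
    return generate_library(SynthConfig.network_benchmark(seed=42))


@pytest.fixture(scope="session")
def network_sweep(network_library):
    """The full 0-10% cutoff sweep on the network benchmark (shared: costly)."""
    from specdenoise import sweep

    return sweep(network_library)


def random_spectrum(rng, n_peaks=8, grid=None, precursor=None, id="r"):
    """Random test spectrum; a coarse m/z grid makes cross-spectrum matches likely."""
    if grid is not None:
        mz = rng.choice(grid, size=n_peaks, replace=False) + rng.uniform(
            -0.004, 0.004, size=n_peaks)
    else:
        mz = rng.uniform(50, 450, size=n_peaks)
    intensity = rng.uniform(1.0, 100.0, size=n_peaks)
    return make_spectrum(np.sort(mz), intensity[np.argsort(mz)], id=id,
                         precursor_mz=precursor or float(rng.uniform(460, 700)))
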