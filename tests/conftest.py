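import numpy as np
import pytest

from trfret import (
    AcquisitionSettings,
    DistanceDistribution,
    ProbePair,
    RadialGrid,
    SubPopulation,
    TimeGrid,
    benchmark_grid,
    benchmark_mixture,
    benchmark_populations,
)


@pytest.fixture(scope="session")
def probes():
    return ProbePair(r0=32.0, tau_d0=10.0, tau_a0=4.0)


@pytest.fixture(scope="session")
def grid():
    return benchmark_grid()


@pytest.fixture(scope="session")
def rigid(grid):
    return benchmark_populations()[0]


@pytest.fixture(scope="session")
def flexible(grid):
    return benchmark_populations()[1]


@pytest.fixture(scope="session")
def mixture_half():
    return benchmark_mixture(0.5)


@pytest.fixture(scope="session")
def channel_times():
    return TimeGrid(dt=0.0122, n_steps=3000)


@pytest.fixture(scope="session")
def fast_acq():
    """Reduced acquisition for fit tests that exercise machinery, not scale."""
    return AcquisitionSettings(
        n_channels=750, dt=0.05, peak_counts=10000.0, irf_fwhm_ps=50.0,
        irf_center_channel=8,
    )
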