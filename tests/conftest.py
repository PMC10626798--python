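import pytest

from archatac import SimConfig, Simulation
from archatac.tracks import coverage_track


@pytest.fixture(scope="session")
def default_sim() -> Simulation:
    """The full-size default genome; shared to amortize the build cost."""
    return Simulation(SimConfig())


@pytest.fixture(scope="session")
def small_sim() -> Simulation:
    """Miniature genome for fast property/calibration loops."""
    return Simulation(SimConfig.small())


@pytest.fixture(scope="session")
def default_atac(default_sim):
    return default_sim.atac("exponential", 200_000, 1)


@pytest.fixture(scope="session")
def default_atac_track(default_sim, default_atac):
    return coverage_track(default_atac, default_sim.genome)


@pytest.fixture(scope="session")
def default_kas(default_sim):
    return default_sim.kas("exponential", 200_000, 1)
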