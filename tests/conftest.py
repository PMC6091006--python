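import pytest

from hml2profiler.simulate import SimulationConfig, simulate_locus_family


@pytest.fixture(scope="session")
def family():
    """Default synthetic paralog family (20 loci + retrocopy, seed 1)."""
    return simulate_locus_family(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def gag_profile(family):
    return family.profile("gag")


@pytest.fixture(scope="session")
def env_profile(family):
    return family.profile("env600nt")


@pytest.fixture(scope="session")
def small_family():
    """10 distinguishable loci, no identical pair/retrocopy (oracle tests)."""
    return simulate_locus_family(
        SimulationConfig(seed=2, n_loci=10, identical_pair=False, retrocopy=False)
    )
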