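import pytest
from hypothesis import settings

from satdna import simulate as sim

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def family40() -> sim.Family:
    """The 43 bp dimeric-HOR family at its default (study) calibration."""
    return sim.build_family(sim.pive40_like(), seed=7)


@pytest.fixture(scope="session")
def family180() -> sim.Family:
    """The 177 bp column-heterogeneous family at its default calibration."""
    return sim.build_family(sim.pive180_like(), seed=7)


@pytest.fixture(scope="session")
def small_genome(family40, family180) -> sim.Genome:
    return sim.build_genome([family40, family180], seed=5,
                            array_length_bp=8000, background_bp=20000)
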