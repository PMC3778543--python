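import numpy as np
import pytest

from pgsr import simulate as sim
from pgsr.screening import DriverSet


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.27, 0.26, 0.23, 0.01] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))


@pytest.fixture(scope="session")
def community():
    return sim.make_community(seed=3)


@pytest.fixture(scope="session")
def community_drivers(community):
    return DriverSet.from_sequences(
        list(community.drivers.values()), community.driver_host
    )


@pytest.fixture(scope="session")
def fixture_tables(community):
    return sim.make_fixture_tables(community, seed=3)


@pytest.fixture(scope="session")
def cohort():
    return sim.make_enterotype_cohort(seed=11)
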