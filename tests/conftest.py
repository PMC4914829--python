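import numpy as np
import pytest

from lamshift.damid import FragmentMap
from lamshift.synthetic import (
    SimParams,
    make_genome,
    plant_architecture,
    simulate_damid_counts,
)


@pytest.fixture(scope="session")
def small_genome():
    return make_genome(7, 2, 6_000_000)


@pytest.fixture(scope="session")
def small_arch(small_genome):
    return plant_architecture(
        small_genome,
        n_lads=8,
        shared_fraction=1.0,
        n_ip=3,
        n_pi=3,
        size_range=(300_000, 600_000),
        seed=8,
        n_genes=600,
    )


@pytest.fixture(scope="session")
def small_fragmap(small_genome):
    return FragmentMap.from_sequences(small_genome.sequence)


@pytest.fixture(scope="session")
def small_counts(small_arch, small_fragmap):
    return simulate_damid_counts(
        small_arch, small_fragmap, SimParams(seed=9, depth=2.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
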