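from collections import Counter

import pytest

from pharmtrace import (
    PathMultiset,
    Policy,
    reconstruct,
    shortfall_example,
    simulate,
    worked_example,
)
from pharmtrace.simulate import SimulationConfig


def path_multiset_counter(paths):
    """Multiset of (entity sequence, date sequence, quantity) triples."""
    return Counter((p.path, p.dates, p.quantity) for p in paths)


@pytest.fixture
def worked():
    return worked_example()


@pytest.fixture
def shortfall():
    return shortfall_example()


@pytest.fixture
def worked_result(worked):
    return reconstruct(worked.transactions, policy=Policy.FIFO)


@pytest.fixture
def small_sim():
    """A modest random scenario with a few hundred completed paths."""
    return simulate(SimulationConfig(seed=11, horizon_days=60))


@pytest.fixture
def small_multiset(small_sim):
    return PathMultiset(small_sim.ledger.completed_paths)
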