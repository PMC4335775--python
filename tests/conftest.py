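import numpy as np
import pytest
from hypothesis import settings

from pombenet.evolution import ESConfig, Genotype, harvest
from pombenet.fission_yeast import cell_cycle_sequence, wildtype
from pombenet.network import ThresholdNetwork, UpdateScheme
from pombenet.neutral import build_graph

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

HARVEST_SEED = 2026
HARVEST_COUNT = 200


@pytest.fixture(scope="session")
def wt():
    return wildtype()


@pytest.fixture(scope="session")
def sequence():
    return cell_cycle_sequence()


@pytest.fixture
def parallel():
    return UpdateScheme("parallel")


def random_network(rng: np.random.Generator, n: int) -> ThresholdNetwork:
    """Random threshold network over the allowed value sets (test helper)."""
    W = rng.choice([-2, -1, 0, 1, 2], size=(n, n))
    theta2 = rng.choice([-4, -2, -1, 0, 1, 2, 4], size=n)
    return ThresholdNetwork(tuple(f"v{i}" for i in range(n)), W, theta2)


@pytest.fixture(scope="session")
def scaled_harvest():
    """A 200-network harvest at the study defaults, shared across tests."""
    return harvest(HARVEST_COUNT, ESConfig(), seed=HARVEST_SEED)


@pytest.fixture(scope="session")
def scaled_graph(scaled_harvest, wt):
    return build_graph(scaled_harvest, Genotype.of(wt))
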