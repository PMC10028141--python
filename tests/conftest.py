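import numpy as np
import pytest

from symptomnet.datasets import Network, SymptomDataset, items_for_nodes
from symptomnet.simulate import GroupSimSpec, make_true_network, sample_group


@pytest.fixture(scope="session")
def chain_network() -> Network:
    """3-node chain: PHQ.1 -0.5- PHQ.2 -0.25- PHQ.3."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.5
    w[1, 2] = w[2, 1] = 0.25
    return Network(["PHQ.1", "PHQ.2", "PHQ.3"], w)


@pytest.fixture(scope="session")
def small_true_network():
    """8-node sparse ground truth used across estimation tests."""
    return make_true_network(3, 2, 3, within_weight=0.4, density=0.5, seed=2)


@pytest.fixture(scope="session")
def ordinal_dataset(small_true_network) -> SymptomDataset:
    return sample_group(GroupSimSpec("A", 400, small_true_network, seed=101))


def make_dataset(scores: np.ndarray, group: str = "G") -> SymptomDataset:
    """Wrap a raw integer score matrix (columns named PHQ.1, PHQ.2, ...)."""
    scores = np.asarray(scores)
    nodes = [f"PHQ.{j + 1}" for j in range(scores.shape[1])]
    return SymptomDataset(
        items_for_nodes(nodes), scores, np.full(scores.shape[0], group, dtype=object)
    )
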