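import numpy as np
import pytest

from beliefnet import GroundTruth, WeightedNetwork, make_ground_truth


@pytest.fixture
def chain3() -> GroundTruth:
    """3-node chain with precision [[2,1,0],[1,2,1],[0,1,2]]."""
    return GroundTruth(
        np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 1.0], [0.0, 1.0, 2.0]]),
        discretization_levels="continuous",
    )


@pytest.fixture
def path3_net() -> WeightedNetwork:
    """A - B (w=0.5), B - C (w=0.5)."""
    w = np.array([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
    return WeightedNetwork(w, ["A", "B", "C"])


def net_from_edges(labels, edges) -> WeightedNetwork:
    idx = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for a, b, weight in edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = weight
    return WeightedNetwork(w, list(labels))


@pytest.fixture
def chain_truth10() -> GroundTruth:
    return make_ground_truth(10, structure="chain", seed=7, levels="continuous")
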