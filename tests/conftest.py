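import numpy as np
import pytest

from netswarm import (
    ExpressionDataset,
    GroundTruthNetwork,
    InfluenceResult,
    TrainConfig,
    aggregate_influence,
    generate_truth_network,
    simulate_expression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_network():
    """10-gene DAG with mixed-sign weights."""
    return generate_truth_network(10, 12, seed=3)


@pytest.fixture
def small_dataset(small_network):
    return simulate_expression(small_network, 40, noise_sd=0.5, seed=4)


@pytest.fixture
def hand_influence():
    """The 3x3 hand-checked influence matrix used across ranking tests.

    Off-diagonals: (0,1)=2, (0,2)=-1, (1,2)=3, (2,0)=1; row |sums| give
    driver scores (3, 3, 1); column |sums| give target scores (1, 2, 4).
    """
    mean = np.array(
        [
            [0.0, 2.0, -1.0],
            [0.0, 0.0, 3.0],
            [1.0, 0.0, 0.0],
        ]
    )
    consistency = (mean != 0).astype(float)
    return InfluenceResult(
        gene_ids=["gA", "gB", "gC"],
        mean_influence=mean,
        sd_influence=np.zeros((3, 3)),
        sign_consistency=consistency,
        n_resamples=1,
    )


@pytest.fixture
def two_group_dataset():
    """30 + 30 samples, 20 genes, effect of size 3 planted in 5 known genes."""
    from netswarm import add_group_effect

    net = generate_truth_network(20, 10, seed=8)
    ds = simulate_expression(net, 60, noise_sd=0.2, seed=9)
    labels = ["young"] * 30 + ["aged"] * 30
    planted = ["g2", "g5", "g11", "g14", "g19"]
    return add_group_effect(ds, labels, planted, 3.0), planted
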