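"""Planted-network benchmark protocols.

These functions bundle the package's standard self-evaluation experiments:
simulate data from a known directed network, run the swarm, and measure how
well the inferred influence matrix recovers the planted structure. They exist
so that the same protocol is runnable from tests, scripts and user code
without copy-pasting experiment code.

Measures
--------
* **Edge-recovery AUROC** — rank every ordered gene pair by |mean influence|
  and score separation of planted pairs (either orientation counts as
  positive, since an undirected correlation footprint is visible both ways)
  from absent pairs. Computed as the Mann–Whitney rank statistic.
* **Sign recovery** — fraction of planted edges whose mean influence carries
  the planted weight's sign, in the planted direction.
* **Linear/OLS equivalence** — with a linear activation, one hidden unit, no
  weight penalty and training run to convergence, the swarm's mean influence
  columns must match ordinary-least-squares coefficients of each gene
  regressed on all others (the closed-form oracle for the linear-Gaussian
  simulator); reported as the worst column-wise relative error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import ExpressionDataset
from .mlp import TrainConfig
from .swarm import InfluenceResult, infer_influence, make_resample_plan
from .synthetic import GroundTruthNetwork, generate_truth_network, simulate_expression

__all__ = [
    "auroc",
    "chain_network",
    "ols_influence_oracle",
    "PlantedRecovery",
    "planted_recovery",
    "linear_ols_max_relative_error",
]


def auroc(labels, scores) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def chain_network(n_genes: int, weight: float = 0.7) -> GroundTruthNetwork:
    """A directed chain g0 -> g1 -> ... with constant weight.

    Every gene is substantively connected, so all regression targets are
    well posed — the benchmark instance for the OLS-equivalence check.
    """
    return GroundTruthNetwork(
        n_genes, tuple((i, i + 1, weight) for i in range(n_genes - 1))
    )


def ols_influence_oracle(dataset: ExpressionDataset) -> np.ndarray:
    """Closed-form influence oracle: standardized all-but-one regressions.

    Column j holds the OLS coefficients of gene j regressed on all other
    genes, all variables z-scored on the full dataset; the diagonal is zero.
    This is what the swarm's mean influence converges to for a linear
    activation trained to convergence without regularization.
    """
    values = dataset.values
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
    z = z.T  # samples x genes
    g = dataset.n_genes
    oracle = np.zeros((g, g))
    for j in range(g):
        idx = np.arange(g) != j
        x = np.column_stack([z[:, idx], np.ones(z.shape[0])])
        beta = np.linalg.lstsq(x, z[:, j], rcond=None)[0][:-1]
        oracle[idx, j] = beta
    return oracle


@dataclass(frozen=True)
class PlantedRecovery:
    """Outcome of one planted-network recovery experiment."""

    auroc: float
    sign_recovery: float
    network: GroundTruthNetwork
    result: InfluenceResult


def planted_recovery(
    generator_seed: int,
    n_genes: int = 30,
    n_edges: int = 15,
    weight_low: float = 0.8,
    weight_high: float = 1.5,
    negative_fraction: float = 0.2,
    n_samples: int = 60,
    noise_sd: float = 0.5,
    n_resamples: int = 25,
    train_fraction: float = 0.8,
    train_config: TrainConfig | None = None,
) -> PlantedRecovery:
    """Simulate from a random planted DAG, infer, and score the recovery.

    Defaults are the package's reference benchmark conditions: 30 genes with
    15 planted edges of magnitude 0.8–1.5 (20% negative), 60 samples, and a
    25-resample swarm of 2-hidden-unit tanh networks.
    """
    network = generate_truth_network(
        n_genes, n_edges, weight_low, weight_high, negative_fraction, seed=generator_seed
    )
    dataset = simulate_expression(
        network, n_samples, noise_sd=noise_sd, seed=generator_seed + 1000
    )
    plan = make_resample_plan(n_samples, n_resamples, train_fraction, seed=generator_seed)
    config = train_config or TrainConfig(seed=generator_seed)
    result = infer_influence(dataset, config, plan)

    adjacency = network.adjacency()
    mean = result.mean_influence
    labels, scores = [], []
    for i in range(n_genes):
        for j in range(n_genes):
            if i == j:
                continue
            labels.append(adjacency[i, j] != 0 or adjacency[j, i] != 0)
            scores.append(abs(mean[i, j]))
    sign_hits = sum(
        1 for s, t, w in network.edges if np.sign(mean[s, t]) == np.sign(w)
    )
    return PlantedRecovery(
        auroc=auroc(labels, scores),
        sign_recovery=sign_hits / network.n_edges if network.n_edges else float("nan"),
        network=network,
        result=result,
    )


def linear_ols_max_relative_error(
    seed: int,
    n_genes: int = 10,
    n_samples: int = 200,
    chain_weight: float = 0.7,
    noise_sd: float = 1.0,
    n_resamples: int = 25,
    train_fraction: float = 0.9,
    max_epochs: int = 1000,
) -> float:
    """Worst column-wise relative error of mean influence vs. the OLS oracle.

    Uses the chain benchmark instance (well conditioned, every column well
    posed), a linear activation with one hidden unit, no weight penalty, and
    full-length training with early stopping disabled.
    """
    network = chain_network(n_genes, chain_weight)
    dataset = simulate_expression(network, n_samples, noise_sd=noise_sd, seed=seed)
    config = TrainConfig(
        n_hidden=1,
        activation="linear",
        l2_penalty=0.0,
        learning_rate=0.05,
        momentum=0.9,
        max_epochs=max_epochs,
        patience=max_epochs,
        early_stopping=False,
        seed=seed,
    )
    plan = make_resample_plan(n_samples, n_resamples, train_fraction, seed=seed)
    result = infer_influence(dataset, config, plan)
    oracle = ols_influence_oracle(dataset)
    errors = []
    for j in range(n_genes):
        idx = np.arange(n_genes) != j
        diff = result.mean_influence[idx, j] - oracle[idx, j]
        errors.append(np.linalg.norm(diff) / np.linalg.norm(oracle[idx, j]))
    return float(max(errors))
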