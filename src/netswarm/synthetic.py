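"""Synthetic benchmark data with a planted, known-truth interaction network.

Real two-condition muscle transcriptome studies (young vs. aged, pre vs. post
training) provide no ground truth about which gene influences which, so the
inference engine is exercised on data simulated from a planted directed
network instead. The generative model is deliberately the simplest one under
which the network's linearized influence has an exact oracle:

* the truth network is a random DAG with signed, weighted edges;
* expression follows a linear-Gaussian structural model — root genes are
  standard normal, every other gene is the weighted sum of its parents plus
  Gaussian noise, evaluated in topological order;
* condition contrasts are additive mean shifts on a chosen gene subset.

Under this model the influence of gene *i* on gene *j*, as the swarm defines
it, coincides with a regression coefficient, which recovery tests can compute
independently. The DAG restriction applies to generation only; the inference
engine makes no acyclicity assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import ExpressionDataset
from .errors import CapacityError, DataError, ParameterError, ShapeError, TopologyError

__all__ = [
    "GroundTruthNetwork",
    "generate_truth_network",
    "simulate_expression",
    "add_group_effect",
]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A planted directed, signed, weighted gene network.

    ``edges`` holds ``(source, target, weight)`` triples over gene indices
    ``0 .. n_genes-1``. The graph must be simple (no self-edges, no duplicate
    ordered pairs) and acyclic, so expression can be simulated in topological
    order.
    """

    n_genes: int
    edges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        object.__setattr__(
            self, "edges", tuple((int(s), int(t), float(w)) for s, t, w in self.edges)
        )
        pairs = [(s, t) for s, t, _ in self.edges]
        for s, t in pairs:
            if s == t:
                raise TopologyError(f"self-edge on gene {s}")
            if not (0 <= s < self.n_genes and 0 <= t < self.n_genes):
                raise ShapeError(f"edge ({s}, {t}) references a gene outside 0..{self.n_genes - 1}")
        if len(set(pairs)) != len(pairs):
            raise TopologyError("duplicate (source, target) pair")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise TopologyError("network contains a directed cycle")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_genes))
        g.add_weighted_edges_from(self.edges)
        return g

    def adjacency(self) -> np.ndarray:
        """Signed weight matrix W with W[source, target] = weight, 0 elsewhere."""
        w = np.zeros((self.n_genes, self.n_genes))
        for s, t, weight in self.edges:
            w[s, t] = weight
        return w

    def has_edge(self, source: int, target: int) -> bool:
        return any(s == source and t == target for s, t, _ in self.edges)

    # -- plain-text persistence (3-column TSV) -----------------------------

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\n")
            for s, t, w in self.edges:
                fh.write(f"{s}\t{t}\t{w!r}\n")

    @classmethod
    def read_tsv(cls, path, n_genes: int) -> "GroundTruthNetwork":
        edges = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() != "source\ttarget\tweight":
                raise DataError(f"unexpected network header: {header!r}")
            for line in fh:
                s, t, w = line.rstrip("\n").split("\t")
                edges.append((int(s), int(t), float(w)))
        return cls(n_genes=n_genes, edges=tuple(edges))


def generate_truth_network(
    n_genes: int,
    n_edges: int,
    weight_low: float = 0.8,
    weight_high: float = 1.5,
    negative_fraction: float = 0.2,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Sample a random DAG with signed uniform weights.

    A topological order is drawn uniformly at random; ``n_edges`` distinct
    ordered pairs compatible with that order are then drawn without
    replacement. Weight magnitudes are uniform in ``[weight_low, weight_high]``
    and each sign is negative with probability ``negative_fraction``.

    Raises
    ------
    CapacityError
        If ``n_edges`` exceeds the DAG maximum ``n_genes * (n_genes - 1) / 2``.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be positive")
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges:
        raise CapacityError(
            f"n_edges={n_edges} exceeds the DAG maximum of {max_edges} for {n_genes} genes"
        )
    if n_edges < 0:
        raise ParameterError("n_edges must be non-negative")
    if not (0.0 < weight_low <= weight_high):
        raise ParameterError("require 0 < weight_low <= weight_high")
    if not (0.0 <= negative_fraction <= 1.0):
        raise ParameterError("negative_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    # All ordered pairs (earlier, later) in the sampled topological order.
    candidates = [
        (int(order[i]), int(order[j]))
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
    ]
    chosen = rng.choice(len(candidates), size=n_edges, replace=False) if n_edges else np.empty(0, int)
    magnitudes = rng.uniform(weight_low, weight_high, size=n_edges)
    signs = np.where(rng.random(n_edges) < negative_fraction, -1.0, 1.0)
    edges = tuple(
        (candidates[k][0], candidates[k][1], float(m * s))
        for k, m, s in zip(chosen, magnitudes, signs)
    )
    return GroundTruthNetwork(n_genes=n_genes, edges=edges)


def simulate_expression(
    network: GroundTruthNetwork,
    n_samples: int,
    noise_sd: float = 0.5,
    seed: int = 0,
    group_label: str = "all",
) -> ExpressionDataset:
    """Draw expression samples from the linear-Gaussian structural model.

    Root genes (no incoming edges) are independent standard normal per sample;
    every other gene is ``sum(weight * parent) + Normal(0, noise_sd)``,
    evaluated in (deterministic lexicographic) topological order. All samples
    carry a single default group label.
    """
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    graph = network.to_networkx()
    if not nx.is_directed_acyclic_graph(graph):
        raise TopologyError("network contains a directed cycle")

    rng = np.random.default_rng(seed)
    values = np.zeros((network.n_genes, n_samples))
    for gene in nx.lexicographical_topological_sort(graph):
        parents = list(graph.predecessors(gene))
        if not parents:
            values[gene] = rng.standard_normal(n_samples)
        else:
            signal = sum(graph.edges[p, gene]["weight"] * values[p] for p in parents)
            values[gene] = signal + (rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else 0.0)

    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(network.n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=values,
        group_labels=[group_label] * n_samples,
    )


def add_group_effect(
    dataset: ExpressionDataset,
    group_assignment: list[str],
    affected_genes: list[str],
    effect_size: float,
) -> ExpressionDataset:
    """Plant a two-condition contrast as an additive mean shift.

    ``group_assignment`` must name exactly two groups (one label per sample);
    every value of each gene in ``affected_genes`` is increased by exactly
    ``effect_size`` in the *second* group, where "second" means the label that
    appears second in order of first appearance. Returns a copy; group labels
    are replaced by the assignment.
    """
    if len(group_assignment) != dataset.n_samples:
        raise ShapeError(
            f"group_assignment has {len(group_assignment)} labels for {dataset.n_samples} samples"
        )
    distinct = list(dict.fromkeys(str(g) for g in group_assignment))
    if len(distinct) != 2:
        raise ParameterError(f"group_assignment must name exactly 2 groups, got {len(distinct)}")
    rows = [dataset.gene_index(g) for g in affected_genes]  # raises GeneLookupError

    out = dataset.copy()
    second = distinct[1]
    cols = np.flatnonzero(np.asarray([str(g) for g in group_assignment]) == second)
    for r in rows:
        out.values[r, cols] += effect_size
    return ExpressionDataset(
        gene_ids=out.gene_ids,
        sample_ids=out.sample_ids,
        values=out.values,
        group_labels=[str(g) for g in group_assignment],
        subject_ids=out.subject_ids,
    )
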