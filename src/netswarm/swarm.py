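"""Swarm inference: from an expression matrix to a directed influence matrix.

For each Monte Carlo resample of the samples and each gene *j* taken as
output, one shallow MLP is trained to predict gene *j*'s standardized
expression from all other genes (also standardized, with statistics from the
training split). The linearized influence of each predictor on the trained
network fills column *j* of a per-resample G x G matrix (diagonal forced to
zero). The per-resample matrices are then integrated element-wise into a
single result: the mean influence (signed strength and direction of each
candidate interaction), its standard deviation across resamples, and the sign
consistency — the fraction of resamples agreeing with the sign of the mean,
which is ~1 for stable interactions and ~0.5 for noise.

Both orientations (i, j) and (j, i) are retained as distinct directed
influences: they come from different models and are never symmetrized.
Per-(resample, gene) seeds are derived deterministically from the base
training seed, so the result is independent of loop order.
"""

from __future__ import annotations

import gzip
import io
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .errors import CapacityError, ParameterError, ShapeError, TrainingDivergenceError
from .mlp import MLPModel, TrainConfig, linearized_influence, standardize_train_val, train_mlp

__all__ = [
    "ResamplePlan",
    "InfluenceResult",
    "make_resample_plan",
    "infer_influence",
    "aggregate_influence",
]


@dataclass(frozen=True)
class ResamplePlan:
    """Monte Carlo cross-validation splits over sample indices."""

    splits: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        for k, (tr, va) in enumerate(self.splits):
            if len(va) < 1:
                raise ShapeError(f"split {k} has an empty validation set")
            if set(tr) & set(va):
                raise ShapeError(f"split {k} has overlapping train/validation indices")

    @property
    def n_resamples(self) -> int:
        return len(self.splits)


@dataclass
class InfluenceResult:
    """Aggregated G x G signed influence with dispersion and sign stability.

    ``mean_influence[i, j]`` is the aggregated signed influence of gene *i* on
    gene *j*; diagonals of all matrices are exactly zero.
    """

    gene_ids: list[str]
    mean_influence: np.ndarray
    sd_influence: np.ndarray
    sign_consistency: np.ndarray
    n_resamples: int

    def __post_init__(self) -> None:
        g = len(self.gene_ids)
        self.mean_influence = np.asarray(self.mean_influence, dtype=float)
        self.sd_influence = np.asarray(self.sd_influence, dtype=float)
        self.sign_consistency = np.asarray(self.sign_consistency, dtype=float)
        for name, m in (
            ("mean_influence", self.mean_influence),
            ("sd_influence", self.sd_influence),
            ("sign_consistency", self.sign_consistency),
        ):
            if m.shape != (g, g):
                raise ShapeError(f"{name} must be {g}x{g}, got {m.shape}")
            if np.any(np.diag(m) != 0):
                raise ShapeError(f"{name} must have a zero diagonal")
        if np.any(self.sd_influence < 0):
            raise ShapeError("sd_influence must be non-negative")
        if np.any((self.sign_consistency < 0) | (self.sign_consistency > 1)):
            raise ShapeError("sign_consistency must lie in [0, 1]")
        if self.n_resamples < 1:
            raise ParameterError("n_resamples must be >= 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    # -- persistence: gzip-compressed TSV trio -----------------------------

    def save(self, prefix: str) -> dict[str, str]:
        """Write mean/sd/consistency as gzipped TSVs with gene-id headers."""
        paths = {}
        for tag, m in (
            ("mean", self.mean_influence),
            ("sd", self.sd_influence),
            ("consistency", self.sign_consistency),
        ):
            path = f"{prefix}.{tag}.tsv.gz"
            frame = pd.DataFrame(m, index=self.gene_ids, columns=self.gene_ids)
            # mtime=0 keeps the gzip stream byte-identical across runs.
            with open(path, "wb") as raw, gzip.GzipFile(
                fileobj=raw, mode="wb", mtime=0
            ) as gz, io.TextIOWrapper(gz, encoding="utf-8") as fh:
                frame.to_csv(fh, sep="\t", float_format="%.17g")
            paths[tag] = path
        return paths

    @classmethod
    def load(cls, prefix: str, n_resamples: int) -> "InfluenceResult":
        frames = {}
        for tag in ("mean", "sd", "consistency"):
            with gzip.open(f"{prefix}.{tag}.tsv.gz", "rt", encoding="utf-8") as fh:
                frames[tag] = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
        return cls(
            gene_ids=[str(g) for g in frames["mean"].index],
            mean_influence=frames["mean"].to_numpy(),
            sd_influence=frames["sd"].to_numpy(),
            sign_consistency=frames["consistency"].to_numpy(),
            n_resamples=n_resamples,
        )


def make_resample_plan(
    n_samples: int,
    n_resamples: int = 25,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> ResamplePlan:
    """Draw independent uniform train/validation splits without replacement.

    Each split assigns ``floor(n_samples * train_fraction)`` samples to
    training and the remainder to validation.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ParameterError("train_fraction must lie strictly in (0, 1)")
    if n_resamples < 1:
        raise ParameterError("n_resamples must be >= 1")
    n_train = int(np.floor(n_samples * train_fraction))
    if n_train < 2 or n_samples - n_train < 1:
        raise CapacityError(
            f"n_samples={n_samples} with train_fraction={train_fraction} leaves "
            f"{n_train} train / {n_samples - n_train} validation samples; need >= 2 / >= 1"
        )
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_resamples):
        perm = rng.permutation(n_samples)
        splits.append(
            (tuple(sorted(int(i) for i in perm[:n_train])),
             tuple(sorted(int(i) for i in perm[n_train:])))
        )
    return ResamplePlan(splits=tuple(splits), train_fraction=train_fraction, seed=seed)


def _gene_key(gene_id: str) -> int:
    return zlib.crc32(gene_id.encode("utf-8"))


def _initial_model(
    config: TrainConfig, resample: int, output_gene: str, input_genes: list[str]
) -> MLPModel:
    """Seeded initial weights keyed to gene *identities*, not positions.

    Every W_in row is drawn from a stream seeded by (base seed, resample,
    output gene, input gene), W_out from (base seed, resample, output gene),
    so relabeling-invariant: permuting the dataset's gene order permutes the
    initial weights — and hence the full deterministic training trajectory —
    identically.
    """
    s = config.init_scale
    cj = _gene_key(output_gene)
    rows = [
        np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(resample, cj, 1 + _gene_key(g)))
        ).uniform(-s, s, config.n_hidden)
        for g in input_genes
    ]
    out_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(resample, cj, 0))
    )
    return MLPModel(
        W_in=np.vstack(rows),
        b_hidden=np.zeros(config.n_hidden),
        W_out=out_rng.uniform(-s, s, config.n_hidden),
        b_out=0.0,
        activation=config.activation,
    )


def infer_influence(
    dataset: ExpressionDataset,
    train_config: TrainConfig,
    plan: ResamplePlan,
) -> InfluenceResult:
    """Run the swarm over all (resample, output-gene) pairs and aggregate.

    Raises
    ------
    CapacityError
        If the dataset has fewer than 3 genes.
    TrainingDivergenceError
        Propagated from any member fit, naming the (resample, gene) pair.
    """
    g = dataset.n_genes
    if g < 3:
        raise CapacityError(f"need at least 3 genes, got {g}")
    n = dataset.n_samples
    for k, (tr, va) in enumerate(plan.splits):
        if any(i < 0 or i >= n for i in tr + va):
            raise ShapeError(f"split {k} references a sample index outside 0..{n - 1}")

    samples_by_genes = dataset.values.T  # (samples, genes)
    per_resample: list[np.ndarray] = []
    for r, (tr, va) in enumerate(plan.splits):
        Ztr, Zva, _, _ = standardize_train_val(
            samples_by_genes[list(tr), :], samples_by_genes[list(va), :]
        )
        matrix = np.zeros((g, g))
        for j in range(g):
            idx = np.arange(g) != j
            input_genes = [dataset.gene_ids[i] for i in range(g) if i != j]
            init = _initial_model(train_config, r, dataset.gene_ids[j], input_genes)
            try:
                fit = train_mlp(
                    Ztr[:, idx], Ztr[:, j], Zva[:, idx], Zva[:, j],
                    train_config, initial_model=init,
                )
            except TrainingDivergenceError as err:
                raise TrainingDivergenceError(
                    err.epoch,
                    f"training diverged at epoch {err.epoch} "
                    f"(resample {r}, output gene {dataset.gene_ids[j]})",
                ) from err
            matrix[idx, j] = linearized_influence(fit.model, Ztr[:, idx])
        per_resample.append(matrix)

    return aggregate_influence(per_resample, gene_ids=dataset.gene_ids)


def aggregate_influence(
    per_resample: list[np.ndarray],
    gene_ids: list[str] | None = None,
) -> InfluenceResult:
    """Integrate per-resample influence matrices element-wise.

    Mean and (sample) standard deviation are taken across resamples; sign
    consistency of entry (i, j) is the fraction of resamples whose influence
    shares the sign of the mean (0 where the mean is exactly 0).
    """
    if len(per_resample) < 1:
        raise ShapeError("need at least one per-resample matrix")
    mats = [np.asarray(m, dtype=float) for m in per_resample]
    if any(m.shape != mats[0].shape for m in mats):
        raise ShapeError("per-resample matrices differ in shape")
    if mats[0].ndim != 2 or mats[0].shape[0] != mats[0].shape[1]:
        raise ShapeError(f"matrices must be square, got {mats[0].shape}")
    stack = np.stack(mats)
    g = stack.shape[1]
    if np.any(stack[:, np.arange(g), np.arange(g)] != 0):
        raise ShapeError("per-resample matrices must have zero diagonals")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if len(gene_ids) != g:
        raise ShapeError("gene_ids length does not match matrix size")

    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    ref_sign = np.sign(mean)
    consistency = np.where(
        ref_sign == 0, 0.0, (np.sign(stack) == ref_sign).mean(axis=0)
    )
    np.fill_diagonal(mean, 0.0)
    np.fill_diagonal(sd, 0.0)
    np.fill_diagonal(consistency, 0.0)
    return InfluenceResult(
        gene_ids=list(gene_ids),
        mean_influence=mean,
        sd_influence=sd,
        sign_consistency=consistency,
        n_resamples=stack.shape[0],
    )
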