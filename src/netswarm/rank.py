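"""Driver/target gene scoring and strongest-edge extraction.

A *driver* is a gene with high aggregate outgoing influence, a *target* one
with high aggregate incoming influence. Scores are L1 norms of the rows
(outgoing) and columns (incoming) of the absolute mean-influence matrix: this
rewards both many moderate and a few strong links and is stable under the
standardized-influence scale. Ranks are descending by score with ties broken
by ascending gene id so orderings are reproducible.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .swarm import InfluenceResult

__all__ = ["EdgeRecord", "score_genes", "top_k", "strongest_edges", "write_scores_csv"]

SCORE_COLUMNS = ["gene_id", "driver_score", "target_score", "driver_rank", "target_rank"]


class EdgeRecord(NamedTuple):
    """One ranked directed interaction (strength = |mean influence|)."""

    source: str
    target: str
    strength: float
    sign: int
    consistency: float


def _ranks(scores: pd.Series, gene_ids: list[str]) -> np.ndarray:
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores.iloc[i], gene_ids[i]))
    ranks = np.empty(len(gene_ids), dtype=int)
    ranks[order] = np.arange(1, len(gene_ids) + 1)
    return ranks

def score_genes(result: InfluenceResult) -> pd.DataFrame:
    """Per-gene driver/target scores and ranks.

    Returns a DataFrame with columns ``gene_id, driver_score, target_score,
    driver_rank, target_rank``; driver_score(i) = sum_j |mean(i, j)| and
    target_score(j) = sum_i |mean(i, j)|.
    """
    absolute = np.abs(result.mean_influence)
    table = pd.DataFrame(
        {
            "gene_id": result.gene_ids,
            "driver_score": absolute.sum(axis=1),
            "target_score": absolute.sum(axis=0),
        }
    )
    table["driver_rank"] = _ranks(table["driver_score"], result.gene_ids)
    table["target_rank"] = _ranks(table["target_score"], result.gene_ids)
    return table


def top_k(table: pd.DataFrame, k: int, role: str = "driver") -> list[str]:
    """First ``min(k, G)`` gene ids in the given role's rank order."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if role not in ("driver", "target"):
        raise ParameterError(f"role must be 'driver' or 'target', got {role!r}")
    ordered = table.sort_values(f"{role}_rank")
    return ordered["gene_id"].head(min(k, len(table))).tolist()


def strongest_edges(
    result: InfluenceResult, n: int, min_consistency: float = 0.0
) -> list[EdgeRecord]:
    """Strongest directed interactions passing the sign-consistency filter.

    All off-diagonal entries with nonzero strength and consistency >=
    ``min_consistency``, sorted by descending strength then ascending
    (source, target) ids, truncated to ``n``.
    """
    if not (0.0 <= min_consistency <= 1.0):
        raise ParameterError("min_consistency must lie in [0, 1]")
    if n < 0:
        raise ParameterError("n must be >= 0")
    records = []
    mean = result.mean_influence
    for i in range(result.n_genes):
        for j in range(result.n_genes):
            if i == j or mean[i, j] == 0:
                continue
            if result.sign_consistency[i, j] < min_consistency:
                continue
            records.append(
                EdgeRecord(
                    source=result.gene_ids[i],
                    target=result.gene_ids[j],
                    strength=float(abs(mean[i, j])),
                    sign=int(np.sign(mean[i, j])),
                    consistency=float(result.sign_consistency[i, j]),
                )
            )
    records.sort(key=lambda e: (-e.strength, e.source, e.target))
    return records[:n]


def write_scores_csv(table: pd.DataFrame, path) -> None:
    """Score table as CSV with the documented header, full float precision."""
    table[SCORE_COLUMNS].to_csv(path, index=False, float_format="%.17g")
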