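"""In-memory containers for expression data.

The central object is :class:`ExpressionDataset`: a genes-by-samples matrix of
log-scale expression values with one categorical group label per sample and an
optional subject key for paired designs. It is deliberately a thin, validated
wrapper around a numpy array — heavy lifting happens in the inference and
statistics modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, GeneLookupError, ShapeError

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """Genes × samples expression matrix with sample metadata.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    sample_ids
        Unique sample identifiers, one per matrix column.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; log-scale,
        arbitrary units; no missing values.
    group_labels
        One categorical label per sample; every group must contain at least
        two samples.
    subject_ids
        Optional per-sample subject key for paired designs.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: list[str]
    subject_ids: list[str] | None = None
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group_labels = [str(g) for g in self.group_labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"values must be 2-D, got ndim={self.values.ndim}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ShapeError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample_ids are not unique")
        if len(self.group_labels) != len(self.sample_ids):
            raise ShapeError("group_labels length does not match number of samples")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values contain non-finite entries")
        for grp, cnt in zip(*np.unique(self.group_labels, return_counts=True)):
            if cnt < 2:
                raise DataError(f"group {grp!r} has {cnt} sample(s); every group needs >= 2")
        if self.subject_ids is not None:
            self.subject_ids = [str(s) for s in self.subject_ids]
            if len(self.subject_ids) != len(self.sample_ids):
                raise ShapeError("subject_ids length does not match number of samples")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic queries -----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise GeneLookupError(f"unknown gene id {gene_id!r}") from None

    def groups(self) -> dict[str, np.ndarray]:
        """Map each group label to the array of its sample (column) indices."""
        labels = np.asarray(self.group_labels)
        return {g: np.flatnonzero(labels == g) for g in dict.fromkeys(self.group_labels)}

    # -- derived datasets --------------------------------------------------

    def copy(self) -> "ExpressionDataset":
        return replace(
            self,
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            group_labels=list(self.group_labels),
            subject_ids=None if self.subject_ids is None else list(self.subject_ids),
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        """Restrict to ``gene_ids``, preserving this dataset's gene order."""
        keep = set(gene_ids)
        unknown = keep - set(self.gene_ids)
        if unknown:
            raise GeneLookupError(f"unknown gene id(s): {sorted(unknown)}")
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[idx, :].copy(),
            sample_ids=list(self.sample_ids),
            group_labels=list(self.group_labels),
            subject_ids=None if self.subject_ids is None else list(self.subject_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        """Expression matrix as a DataFrame (genes in rows, samples in columns)."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
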