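"""Relative quantification of qPCR data and the group-comparison tests.

Implements the comparative-Ct workflow used to validate inferred genes on
biopsy material: per sample, the target gene's cycle threshold is normalized
to the mean Ct of one or more housekeeping (reference) genes, then to the
mean of a calibrator group, and exponentiated base 2 (the 2^-ddCt formula).
Group differences of the resulting relative quantities are assessed with a
Welch (unpaired, unequal-variance) t test or a paired t test on per-subject
differences. A Benjamini–Hochberg helper is provided but nothing applies it
by default — reporting is per gene.

Averaging multiple reference genes on the Ct scale generalizes the common
single-housekeeper design (e.g. GAPDH with beta-actin as secondary control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DataError,
    DegenerateDataError,
    GeneLookupError,
    PairingError,
    ShapeError,
)

__all__ = [
    "QpcrTable",
    "RelativeExpression",
    "delta_delta_ct",
    "welch_t_test",
    "paired_t_test",
    "benjamini_hochberg",
]


@dataclass
class QpcrTable:
    """Genes × samples Ct matrix with group labels and reference genes."""

    gene_ids: list[str]
    sample_ids: list[str]
    ct_values: np.ndarray
    group_labels: list[str]
    reference_genes: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group_labels = [str(g) for g in self.group_labels]
        self.reference_genes = [str(g) for g in self.reference_genes]
        self.ct_values = np.asarray(self.ct_values, dtype=float)
        if self.ct_values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ShapeError(
                f"ct_values shape {self.ct_values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ShapeError("group_labels length does not match number of samples")
        if not np.all(np.isfinite(self.ct_values)) or np.any(self.ct_values <= 0):
            raise DataError("all Ct values must be finite and > 0")
        if not self.reference_genes:
            raise DataError("reference_genes must be non-empty")
        missing = set(self.reference_genes) - set(self.gene_ids)
        if missing:
            raise GeneLookupError(f"reference gene(s) not in table: {sorted(missing)}")

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.gene_ids if g not in self.reference_genes]

    @classmethod
    def read_csv(cls, ct_path, groups_path, reference_genes: list[str]) -> "QpcrTable":
        """Ct matrix (rows = genes, columns = samples) plus a sample→group sidecar CSV."""
        ct = pd.read_csv(ct_path, index_col=0)
        groups = pd.read_csv(groups_path)
        if not {"sample_id", "group"} <= set(groups.columns):
            raise DataError("groups CSV needs columns 'sample_id' and 'group'")
        mapping = dict(zip(groups["sample_id"].astype(str), groups["group"].astype(str)))
        sample_ids = [str(s) for s in ct.columns]
        unknown = [s for s in sample_ids if s not in mapping]
        if unknown:
            raise GeneLookupError(f"samples missing a group assignment: {unknown}")
        return cls(
            gene_ids=[str(g) for g in ct.index],
            sample_ids=sample_ids,
            ct_values=ct.to_numpy(dtype=float),
            group_labels=[mapping[s] for s in sample_ids],
            reference_genes=reference_genes,
        )


@dataclass(frozen=True)
class RelativeExpression:
    """Fold change of one sample relative to the calibrator group (unitless)."""

    sample_id: str
    group_label: str
    rq: float


def delta_delta_ct(
    table: QpcrTable, target_gene: str, calibrator_group: str
) -> list[RelativeExpression]:
    """Relative expression per sample by the comparative-Ct (2^-ddCt) method.

    Per sample: dCt = Ct(target) - mean over reference genes of Ct; ddCt =
    dCt - mean of dCt over the calibrator group's samples; rq = 2^-ddCt.
    """
    if target_gene not in table.gene_ids:
        raise GeneLookupError(f"unknown target gene {target_gene!r}")
    if target_gene in table.reference_genes:
        raise GeneLookupError(f"{target_gene!r} is a reference gene, not a target")
    if calibrator_group not in table.group_labels:
        raise GeneLookupError(f"unknown calibrator group {calibrator_group!r}")

    gi = {g: i for i, g in enumerate(table.gene_ids)}
    ref_rows = [gi[g] for g in table.reference_genes]
    ref_mean = table.ct_values[ref_rows, :].mean(axis=0)
    dct = table.ct_values[gi[target_gene], :] - ref_mean
    labels = np.asarray(table.group_labels)
    calibrator_mean = dct[labels == calibrator_group].mean()
    rq = 2.0 ** -(dct - calibrator_mean)
    return [
        RelativeExpression(sample_id=s, group_label=g, rq=float(q))
        for s, g, q in zip(table.sample_ids, table.group_labels, rq)
    ]


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test, two-sided.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataError("groups contain non-finite values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t_test(pre, post) -> tuple[float, float, float]:
    """Paired t test: one-sample t on per-subject differences (post - pre).

    Returns ``(t, df, p)`` with ``df = n - 1``, two-sided.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size != post.size:
        raise PairingError(f"pre has {pre.size} values but post has {post.size}")
    if pre.size < 2:
        raise DataError("need at least 2 pairs")
    if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
        raise DataError("pairs contain non-finite values")
    diff = post - pre
    if np.var(diff, ddof=1) == 0:
        raise DegenerateDataError("all per-subject differences identical; t is undefined")
    res = stats.ttest_1samp(diff, 0.0)
    return float(res.statistic), float(diff.size - 1), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """FDR-adjusted p-values (off by default everywhere in this package)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
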