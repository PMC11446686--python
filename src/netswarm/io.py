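"""Readers and writers for the text formats the pipeline touches.

Expression matrices follow the dominant GEO-style dialect: genes in rows,
samples in columns, tab-delimited with UTF-8 ids, a header row of sample ids
and the gene id in the first column; sample→group assignments live in a
companion two-column TSV. An inclusion filter rejects matrices below a
transcript-count threshold (default 10 000), mirroring the original study's
dataset-selection rule. Interactomes are exported as a SIF file plus edge-
and node-attribute TSVs loadable by standard network-visualization tools
(Cytoscape and friends).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset
from .errors import CapacityError, DataError, FormatError, InclusionError, ParameterError
from .rank import SCORE_COLUMNS, EdgeRecord

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "prefilter_genes",
    "write_interactome",
    "read_edge_attributes",
]

DEFAULT_MIN_TRANSCRIPTS = 10_000


def write_expression_matrix(dataset: ExpressionDataset, path, groups_path) -> None:
    """Write the matrix TSV and its sample→group companion, full precision."""
    dataset.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label="gene_id")
    companion = pd.DataFrame({"sample_id": dataset.sample_ids, "group": dataset.group_labels})
    if dataset.subject_ids is not None:
        companion["subject_id"] = dataset.subject_ids
    companion.to_csv(groups_path, sep="\t", index=False)


def read_expression_matrix(
    path, groups_path, min_transcripts: int = DEFAULT_MIN_TRANSCRIPTS
) -> ExpressionDataset:
    """Parse an expression matrix and apply the transcript-count inclusion filter.

    Raises
    ------
    FormatError
        On duplicate gene ids or missing values (the message lists the
        (gene, sample) coordinates of every missing cell).
    InclusionError
        If the matrix has fewer than ``min_transcripts`` genes; the message
        names the threshold.
    """
    # round_trip parsing keeps the reader a bit-exact inverse of the writer
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    gene_ids = [str(g) for g in frame.index]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise FormatError(f"duplicate gene id(s): {dupes}")
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        rows, cols = np.nonzero(np.isnan(values))
        coords = [(gene_ids[r], str(frame.columns[c])) for r, c in zip(rows, cols)]
        raise FormatError(f"missing values at (gene, sample): {coords}")
    if len(gene_ids) < min_transcripts:
        raise InclusionError(
            f"dataset has {len(gene_ids)} gene transcripts, below the inclusion "
            f"threshold of {min_transcripts}"
        )

    companion = pd.read_csv(groups_path, sep="\t")
    if not {"sample_id", "group"} <= set(companion.columns):
        raise FormatError("groups file needs columns 'sample_id' and 'group'")
    mapping = dict(zip(companion["sample_id"].astype(str), companion["group"].astype(str)))
    sample_ids = [str(s) for s in frame.columns]
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise FormatError(f"samples missing a group assignment: {missing}")
    subject_ids = None
    if "subject_id" in companion.columns:
        smap = dict(zip(companion["sample_id"].astype(str), companion["subject_id"].astype(str)))
        subject_ids = [smap[s] for s in sample_ids]
    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        group_labels=[mapping[s] for s in sample_ids],
        subject_ids=subject_ids,
    )


def prefilter_genes(
    dataset: ExpressionDataset, method: str = "welch", n_keep: int = 200
) -> ExpressionDataset:
    """Keep the most variable or most differentially expressed genes.

    ``method='variance'`` keeps the ``n_keep`` genes with highest variance;
    ``method='welch'`` (two-group designs only) keeps those with the smallest
    Welch-test p-value between the groups. Ties break by ascending gene id;
    the surviving genes keep their original order.
    """
    if method not in ("variance", "welch"):
        raise ParameterError(f"method must be 'variance' or 'welch', got {method!r}")
    if n_keep < 3:
        raise ParameterError("n_keep must be >= 3")
    if n_keep > dataset.n_genes:
        raise CapacityError(f"n_keep={n_keep} exceeds the {dataset.n_genes} genes available")

    if method == "variance":
        # Negate so the sort key is ascending; zero-variance genes rank last.
        key = -dataset.values.var(axis=1, ddof=1)
    else:
        groups = dataset.groups()
        if len(groups) != 2:
            raise DataError(f"welch prefilter needs exactly 2 groups, got {len(groups)}")
        (idx_a, idx_b) = groups.values()
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(
                dataset.values[:, idx_a], dataset.values[:, idx_b], axis=1, equal_var=False
            )
        key = np.where(np.isfinite(res.pvalue), res.pvalue, np.inf)

    order = sorted(range(dataset.n_genes), key=lambda i: (key[i], dataset.gene_ids[i]))
    keep = {dataset.gene_ids[i] for i in order[:n_keep]}
    return dataset.subset_genes([g for g in dataset.gene_ids if g in keep])


def write_interactome(edges: list[EdgeRecord], scores: pd.DataFrame, out_prefix) -> dict[str, str]:
    """Export the inferred interactome for network-visualization tools.

    Writes ``<prefix>.sif`` ("source<TAB>influences<TAB>target", with genes
    that take part in no edge listed alone on their own line), an
    edge-attribute TSV (source, target, strength, sign, consistency) and a
    node-attribute TSV carrying the score table. Returns the paths.
    """
    if scores.empty:
        raise DataError("score table is empty; nothing to export")
    out_prefix = str(out_prefix)
    paths = {
        "sif": f"{out_prefix}.sif",
        "edges": f"{out_prefix}.edges.tsv",
        "nodes": f"{out_prefix}.nodes.tsv",
    }
    connected = {e.source for e in edges} | {e.target for e in edges}
    with open(paths["sif"], "w", encoding="utf-8") as fh:
        for e in edges:
            fh.write(f"{e.source}\tinfluences\t{e.target}\n")
        for gene in scores["gene_id"]:
            if gene not in connected:
                fh.write(f"{gene}\n")
    with open(paths["edges"], "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tstrength\tsign\tconsistency\n")
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{e.strength!r}\t{e.sign}\t{e.consistency!r}\n")
    scores[SCORE_COLUMNS].to_csv(paths["nodes"], sep="\t", index=False, float_format="%.17g")
    return paths


def read_edge_attributes(path) -> list[EdgeRecord]:
    """Inverse of the edge-attribute TSV written by :func:`write_interactome`."""
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "source\ttarget\tstrength\tsign\tconsistency":
            raise FormatError(f"unexpected edge-attribute header: {header!r}")
        for line in fh:
            s, t, strength, sign, consistency = line.rstrip("\n").split("\t")
            records.append(
                EdgeRecord(
                    source=s, target=t, strength=float(strength),
                    sign=int(sign), consistency=float(consistency),
                )
            )
    return records
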