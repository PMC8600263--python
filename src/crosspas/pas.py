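"""Pathway activity scoring (PAS).

Each gene is dichotomized across a cohort's samples at its median: samples
strictly above the median score +1, all others (including ties at the
median) score -1.  A pathway's activity in a sample is the mean of these
±1 scores over the pathway's genes that are present in the matrix, so PAS
lies in [-1, +1] and depends only on within-gene ranks — any strictly
increasing per-gene transform of the expression values (a platform change,
a log, a quantile map) leaves it unchanged.

PAS is always computed within one cohort: the split point is cohort-relative,
and the rank-invariance argument only holds per cohort.

Tie handling matters on discrete data: a gene whose value equals the median
in many samples pushes those samples into the -1 group, so a constant gene
scores -1 everywhere.  This is the conservative reading of "the higher
group" getting +1, and it is the documented default rather than a fact of
the underlying method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class PASMatrix:
    """Pathway/sub-pathway activity scores, features x samples, entries in [-1, 1]."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    # per-feature count of the pathway's genes found in the expression matrix
    present_genes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("PAS matrix shape does not match ids")
        if self.values.size and (np.abs(self.values) > 1 + 1e-12).any():
            raise ValueError("PAS values outside [-1, 1]")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, feature_ids: list[str]) -> "PASMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        present = (
            {f: self.present_genes[f] for f in feature_ids} if self.present_genes else None
        )
        return PASMatrix(list(feature_ids), list(self.sample_ids), self.values[idx], present)

    def subset_samples(self, sample_ids: list[str]) -> "PASMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return PASMatrix(
            list(self.feature_ids), list(sample_ids), self.values[:, idx], self.present_genes
        )


def dichotomize_gene(expression_row: np.ndarray, *, quantile: float = 0.5) -> np.ndarray:
    """Score one gene across samples: +1 strictly above the split point, else -1.

    The split point is the within-cohort quantile (default median).  A
    constant row therefore scores -1 for every sample (logged).
    """
    row = np.asarray(expression_row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ValueError("need a 1-D expression row over >= 2 samples")
    split = np.quantile(row, quantile)
    if (row == row[0]).all():
        logger.warning("constant expression row: all samples scored -1")
    return np.where(row > split, 1, -1)


def dichotomize_matrix(expr: ExpressionMatrix, *, quantile: float = 0.5) -> np.ndarray:
    """Dichotomize every gene at once; returns an int matrix in {-1, +1}."""
    splits = np.quantile(expr.values, quantile, axis=1, keepdims=True)
    n_const = int((expr.values == expr.values[:, :1]).all(axis=1).sum())
    if n_const:
        logger.warning("%d constant gene rows scored -1 everywhere", n_const)
    return np.where(expr.values > splits, 1, -1)


def compute_pas(
    expr: ExpressionMatrix, gene_set: frozenset[str] | set[str], *, quantile: float = 0.5
) -> np.ndarray:
    """PAS vector over samples for one gene set; absent genes are dropped."""
    present = [g for g in expr.gene_ids if g in gene_set]
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    idx = [expr.gene_ids.index(g) for g in present]
    sub = ExpressionMatrix(present, list(expr.sample_ids), expr.values[idx])
    return dichotomize_matrix(sub, quantile=quantile).mean(axis=0)


def compute_pas_matrix(
    expr: ExpressionMatrix, collection: GeneSetCollection, *, quantile: float = 0.5
) -> PASMatrix:
    """PAS for every pathway in a collection; dichotomization done once per gene.

    Pathways with zero present genes are dropped (count logged and recorded);
    an entirely empty result is an error.
    """
    scores = dichotomize_matrix(expr, quantile=quantile).astype(float)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    feature_ids: list[str] = []
    rows: list[np.ndarray] = []
    present_counts: dict[str, int] = {}
    n_dropped = 0
    for pid, (_, genes) in collection.items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        if not idx:
            n_dropped += 1
            continue
        feature_ids.append(pid)
        rows.append(scores[idx].mean(axis=0))
        present_counts[pid] = len(idx)
    if n_dropped:
        logger.warning("dropped %d pathways with no genes in the matrix", n_dropped)
    if not feature_ids:
        raise ValueError("no pathway has any gene present in the expression matrix")
    return PASMatrix(feature_ids, list(expr.sample_ids), np.vstack(rows), present_counts)


def write_pas(pas: PASMatrix, path) -> None:
    pas.to_frame().to_csv(path, sep="\t", float_format="%.10g")
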