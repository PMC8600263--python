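"""Readers, writers and validated domain containers for the pipeline's file formats.

Expression matrices and clinical tables travel as TSV, gene sets as GMT.
Loading validates into three containers — :class:`ExpressionMatrix`,
:class:`SurvivalTable`, :class:`GeneSetCollection` — that the rest of the
package consumes; nothing downstream re-reads files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class LoadError(ValueError):
    """Raised when an input file fails structural validation."""


@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes in rows, samples in columns.

    Values are unitless continuous expression (RNA-seq normalized counts or
    microarray intensities); the scoring downstream only uses within-gene
    ranks, so the normalization scheme does not need to match across cohorts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_genes, n_samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise LoadError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise LoadError("duplicated gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise LoadError("duplicated sample ids")
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 2:
            raise LoadError("need at least 1 gene and 2 samples")
        if np.isnan(self.values).any():
            raise LoadError("missing values present after loading")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass
class SurvivalTable:
    """Per-sample right-censored follow-up: time in days, event 1=death, 0=censored."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if len(self.sample_ids) != len(self.time) or len(self.time) != len(self.event):
            raise LoadError("sample_ids, time and event lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise LoadError("duplicated sample ids in survival table")
        if np.any(self.time <= 0):
            bad = [self.sample_ids[i] for i in np.nonzero(self.time <= 0)[0][:5]]
            raise LoadError(f"non-positive follow-up time for samples {bad}")
        if not np.isin(self.event, [0, 1]).all():
            raise LoadError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "SurvivalTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        cov = self.covariates.iloc[idx] if self.covariates is not None else None
        return SurvivalTable(list(sample_ids), self.time[idx], self.event[idx], cov)


@dataclass
class GeneSetCollection:
    """Named gene sets: pathway_id -> (description, frozenset of gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.sets.items():
            if not genes:
                raise LoadError(f"gene set {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.sets

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def ids(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path,
    *,
    transposed: bool = False,
    duplicate_policy: str = "mean",
    missing_policy: str = "drop",
) -> ExpressionMatrix:
    """Load a genes x samples TSV (header row = sample ids, first column = gene ids).

    ``transposed=True`` accepts samples-in-rows exports. Duplicate gene rows
    are collapsed by ``duplicate_policy`` ("mean" or "max"); rows with missing
    values are dropped (``missing_policy="drop"``) or median-imputed
    (``"impute"``). Collapses and drops are logged.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise LoadError(f"{path}: empty expression file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise LoadError(f"{path}: no data rows/columns")
    if transposed:
        df = df.T
    # locate any non-numeric cell precisely before coercing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LoadError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    df = numeric
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene rows by %s", path, n_dup, duplicate_policy)
        df = df.groupby(level=0, sort=False).agg(duplicate_policy)
    if df.isna().to_numpy().any():
        if missing_policy == "drop":
            n_before = df.shape[0]
            df = df.dropna(axis=0)
            logger.warning("%s: dropped %d gene rows with missing values", path, n_before - df.shape[0])
            if df.shape[0] == 0:
                raise LoadError(f"{path}: all gene rows had missing values")
        elif missing_policy == "impute":
            med = df.median(axis=1)
            df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy(dtype=float)
    )


def write_expression(expr: ExpressionMatrix, path, *, float_format: str = "%.10g") -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format=float_format)


def read_survival(path) -> tuple[SurvivalTable, dict]:
    """Load a clinical TSV with columns sample_id, time, event (extras kept as covariates).

    Rows missing time or event are dropped; the count is returned in the load
    report, mirroring the upstream removal of samples without survival data.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise LoadError(f"{path}: empty survival file") from None
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise LoadError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    complete = df["time"].notna() & df["event"].notna()
    n_drop = int((~complete).sum())
    if n_drop:
        logger.warning("%s: dropped %d rows without survival data", path, n_drop)
    df = df[complete]
    if df.empty:
        raise LoadError(f"{path}: no rows with complete survival data")
    extra = [c for c in df.columns if c not in ("sample_id", "time", "event")]
    cov = df[extra].reset_index(drop=True) if extra else None
    table = SurvivalTable(
        [str(s) for s in df["sample_id"]],
        df["time"].to_numpy(),
        df["event"].to_numpy(),
        cov,
    )
    return table, {"rows_read": len(complete), "drops": n_drop}


def write_survival(surv: SurvivalTable, path) -> None:
    df = pd.DataFrame({"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event})
    if surv.covariates is not None:
        df = pd.concat([df, surv.covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name TAB description TAB gene...``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise LoadError(f"{path}:{lineno}: duplicate pathway id {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise LoadError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = (desc, genes)
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in collection.items():
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def align_cohort(
    expr: ExpressionMatrix, surv: SurvivalTable
) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Restrict both containers to their common samples, in expression order.

    Idempotent; raises :class:`LoadError` when the cohorts share no samples.
    """
    surv_set = set(surv.sample_ids)
    common = [s for s in expr.sample_ids if s in surv_set]
    if not common:
        raise LoadError("expression and survival tables share no sample ids")
    if len(common) < 2:
        raise LoadError("fewer than 2 samples after alignment")
    if common == expr.sample_ids and common == surv.sample_ids:
        return expr, surv
    return expr.subset_samples(common), surv.subset(common)
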