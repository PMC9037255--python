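"""Reading/writing of expression matrices, clinical tables and edge lists.

Expression input is a TSV with gene ids in the first column and sample ids in
the header row.  The gene-level zero-expression filter drops every gene whose
proportion of zero-valued samples reaches the threshold in *any* cohort, so
that all cohorts stay on a common gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import FLOAT_FMT, check_unique

log = logging.getLogger(__name__)

COHORTS = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``cohort`` is a per-sample label in {"tumor", "normal"}.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (G, S), float64
    cohort: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        check_unique(self.gene_ids, "gene ids")
        check_unique(self.sample_ids, "sample ids")
        if not self.cohort:
            self.cohort = ["tumor"] * len(self.sample_ids)
        if len(self.cohort) != len(self.sample_ids):
            raise ValueError("cohort labels do not match sample count")
        bad = set(self.cohort) - set(COHORTS)
        if bad:
            raise ValueError(f"unknown cohort labels: {bad}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("need at least 2 genes and 2 samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes missing from matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return replace(self, gene_ids=list(genes), values=self.values[rows, :])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return replace(
            self,
            sample_ids=list(samples),
            values=self.values[:, cols],
            cohort=[self.cohort[c] for c in cols],
        )

    def concat_samples(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        if other.gene_ids != self.gene_ids:
            raise ValueError("gene sets differ; filter to a common set first")
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=self.sample_ids + other.sample_ids,
            values=np.hstack([self.values, other.values]),
            cohort=self.cohort + other.cohort,
        )


@dataclass
class ClinicalTable:
    """Per-sample survival information: time in days, event indicator in {0,1}."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        check_unique(self.sample_ids, "sample ids")
        if len(self.sample_ids) != len(self.time) or len(self.time) != len(self.event):
            raise ValueError("clinical columns have inconsistent lengths")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("survival time must be positive and finite")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples missing from clinical table: {missing[:5]}")
        rows = [idx[s] for s in samples]
        cov = self.covariates.iloc[rows] if self.covariates is not None else None
        return ClinicalTable(list(samples), self.time[rows], self.event[rows], cov)


def read_expression(path, cohort_label: str = "tumor") -> ExpressionMatrix:
    """Read a genes x samples TSV; duplicate gene rows are collapsed by mean."""
    if cohort_label not in COHORTS:
        raise ValueError(f"cohort_label must be one of {COHORTS}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample columns")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty or malformed expression file")
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in samples]
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        log.info("%s: collapsing %d duplicate gene rows by mean", path, n)
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        cohort=[cohort_label] * df.shape[1],
    )


def write_expression(mat: ExpressionMatrix, path) -> None:
    mat.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: clinical table needs columns {sorted(required)}")
    extra = [c for c in df.columns if c not in required]
    return ClinicalTable(
        sample_ids=[str(s) for s in df["sample"]],
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        covariates=df[extra].copy() if extra else None,
    )


def write_clinical(tab: ClinicalTable, path) -> None:
    df = pd.DataFrame({"sample": tab.sample_ids, "time": tab.time, "event": tab.event})
    if tab.covariates is not None:
        df = pd.concat([df, tab.covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def filter_zero_genes(
    mats: list[ExpressionMatrix], threshold: float = 0.7
) -> list[ExpressionMatrix]:
    """Drop genes whose zero-sample proportion is >= ``threshold`` in any cohort.

    All outputs are restricted to the common surviving genes of the first
    matrix's gene order; gene order is identical across outputs.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not mats:
        return []
    gene_sets = [set(m.gene_ids) for m in mats[1:]]
    common = [g for g in mats[0].gene_ids if all(g in s for s in gene_sets)]
    if not common:
        raise ValueError("input matrices share no genes")
    keep_mask = np.ones(len(common), dtype=bool)
    for m in mats:
        zero_prop = (m.subset_genes(common).values == 0).mean(axis=1)
        keep_mask &= zero_prop < threshold
    keep = [g for g, k in zip(common, keep_mask) if k]
    if not keep:
        raise ValueError("no gene survives the zero-expression filter")
    return [m.subset_genes(keep) for m in mats]


def read_network_edges(path) -> list[tuple[str, str]]:
    """Read a 2-column TSV or SIF ("geneA interaction geneB") edge list."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) == 3:  # SIF: source interaction-type target
                edges.append((parts[0], parts[2]))
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) fields, got {len(parts)}"
                )
    return edges


def write_network_edges(edges: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
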