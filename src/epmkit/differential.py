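"""Two-group differential screening for expression or methylation matrices.

Per feature: optional log2(x+1) transform, Welch t-test, Benjamini-Hochberg
FDR across all tested features, and the strict |logFC| / FDR pass rule.
logFC is mean(group2) - mean(group1) on the (possibly log-transformed) scale;
for methylation beta values the same statistic is the mean beta difference,
interpreted on the |logFC| scale as in the thresholds it is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from ._util import FLOAT_FMT


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # index: feature id; columns logFC, p, fdr, passing
    group1: str
    group2: str
    lfc_cut: float
    fdr_cut: float

    @property
    def passing(self) -> pd.Index:
        return self.table.index[self.table["passing"]]

    def write(self, path) -> None:
        df = self.table.copy()
        df.columns = [
            f"logFC_{self.group2}_vs_{self.group1}" if c == "logFC" else c
            for c in df.columns
        ]
        df.to_csv(path, sep="\t", index_label="feature", float_format=FLOAT_FMT)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_screen(
    matrix: pd.DataFrame,
    labels: pd.Series | dict,
    group1: str,
    group2: str,
    lfc_cut: float = 0.585,
    fdr_cut: float = 0.01,
    log_transform: bool = True,
) -> DifferentialResult:
    """Welch-t differential screen of ``matrix`` rows between two sample groups.

    ``labels`` maps sample id -> group name.  Strict thresholds:
    passing = (|logFC| > lfc_cut) and (fdr < fdr_cut).
    """
    labels = pd.Series(labels)
    g1 = [s for s in matrix.columns if labels.get(s) == group1]
    g2 = [s for s in matrix.columns if labels.get(s) == group2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    if log_transform:
        if np.any(x < 0):
            raise ValueError("log transform requires non-negative values")
        x = np.log2(x + 1.0)
    i1 = [matrix.columns.get_loc(s) for s in g1]
    i2 = [matrix.columns.get_loc(s) for s in g2]
    a, b = x[:, i1], x[:, i2]
    logfc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = ttest_ind(b, a, axis=1, equal_var=False)
    # zero variance in both groups: p undefined by Welch; equal means -> no
    # evidence (p=1), unequal means -> deterministic separation (p=0)
    bad = ~np.isfinite(p)
    if bad.any():
        p = p.copy()
        p[bad & (logfc == 0)] = 1.0
        p[bad & (logfc != 0)] = 0.0
    fdr = bh_adjust(p)
    passing = (np.abs(logfc) > lfc_cut) & (fdr < fdr_cut)
    table = pd.DataFrame(
        {"logFC": logfc, "p": p, "fdr": fdr, "passing": passing}, index=matrix.index
    )
    return DifferentialResult(table, group1, group2, lfc_cut, fdr_cut)


def preprocess_methylation(beta: pd.DataFrame, missing_threshold: float = 0.7) -> pd.DataFrame:
    """Drop sites missing in more than ``missing_threshold`` of samples; fill
    the remaining missing beta values with 0."""
    missing = beta.isna().mean(axis=1)
    kept = beta.loc[missing <= missing_threshold].fillna(0.0)
    if ((kept.to_numpy() < 0) | (kept.to_numpy() > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    return kept
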