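"""Characteristic-edge selection.

Edges are ranked twice: by the tie-corrected Kruskal-Wallis H statistic
contrasting tumor against normal perturbation values, and by the standard
deviation of the perturbation across tumor samples.  The intersection of the
two top-K sets is the characteristic-edge selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, kruskal, rankdata

from ._util import FLOAT_FMT, edge_id
from .epm import Edge, EdgePerturbationMatrix


@dataclass
class EdgeSelection:
    edges: list[Edge]  # selected, deterministic order (KW rank order)
    kw_stat: pd.Series  # per-edge H, indexed by edge id
    kw_p: pd.Series
    sd_tumor: pd.Series
    top_k: int

    def to_frame(self) -> pd.DataFrame:
        sel = {edge_id(e) for e in self.edges}
        df = pd.DataFrame(
            {"H": self.kw_stat, "p": self.kw_p, "sd": self.sd_tumor}
        )
        df["selected"] = [i in sel for i in df.index]
        return df


def kruskal_wallis_edge(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p for >=2 groups.

    All pooled values identical is a degenerate case: H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = kruskal(*groups)
    return float(h), float(p)


def kruskal_wallis_rows(matrix: np.ndarray, group_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group tie-corrected KW over the rows of ``matrix``.

    ``group_mask`` marks columns of group 1; the rest are group 2.  Rows whose
    values are all identical get H = 0, p = 1.
    """
    matrix = np.asarray(matrix, float)
    n1 = int(group_mask.sum())
    n2 = matrix.shape[1] - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    n = matrix.shape[1]
    ranks = rankdata(matrix, axis=1, method="average")
    r1 = ranks[:, group_mask].sum(axis=1)
    r2 = ranks[:, ~group_mask].sum(axis=1)
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / n2) - 3.0 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (n^3 - n), per row
    sorted_rows = np.sort(matrix, axis=1)
    ties = np.zeros(matrix.shape[0])
    for i in range(matrix.shape[0]):
        _, counts = np.unique(sorted_rows[i], return_counts=True)
        ties[i] = np.sum(counts**3 - counts)
    corr = 1.0 - ties / (n**3 - n)
    degenerate = corr <= 0  # all values identical
    h = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, corr))
    p = np.where(degenerate, 1.0, chi2.sf(h, df=1))
    return h, p


def select_edges(epm: EdgePerturbationMatrix, top_k: int = 30000) -> EdgeSelection:
    """Intersect the top-K KW-different edges with the top-K highest-SD edges.

    Statistics are computed on the untransformed perturbation values.  Ties at
    the top-K boundary are broken deterministically (KW: p ascending then edge
    id; SD: edge id).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    tumor = epm.tumor_mask()
    if tumor.all() or not tumor.any():
        raise ValueError("both tumor and normal cohorts are required")
    ids = [edge_id(e) for e in epm.edges]
    h, p = kruskal_wallis_rows(epm.perturbation, tumor)
    sd = epm.perturbation[:, tumor].std(axis=1, ddof=1)

    kw_order = sorted(range(len(ids)), key=lambda i: (-h[i], p[i], ids[i]))
    sd_order = sorted(range(len(ids)), key=lambda i: (-sd[i], ids[i]))
    kw_top = kw_order[:top_k]
    sd_top = set(sd_order[:top_k])
    selected = [epm.edges[i] for i in kw_top if i in sd_top]
    if not selected:
        raise ValueError(
            f"top-{top_k} KW and SD rankings do not intersect; increase top_k"
        )
    return EdgeSelection(
        edges=selected,
        kw_stat=pd.Series(h, index=ids, name="H"),
        kw_p=pd.Series(p, index=ids, name="p"),
        sd_tumor=pd.Series(sd, index=ids, name="sd"),
        top_k=top_k,
    )


def write_selection(sel: EdgeSelection, path) -> None:
    sel.to_frame().to_csv(path, sep="\t", index_label="edge", float_format=FLOAT_FMT)
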