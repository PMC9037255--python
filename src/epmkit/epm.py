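"""Edge-perturbation matrix (EPM) construction.

Within each sample, genes are ranked by expression (ascending, 1-based,
average ties).  For a network edge e = (i, j) in canonical order the delta
rank is

    delta[e, s] = rank(i, s) - rank(j, s)

The normal benchmark delta-rank vector is obtained by ranking the mean normal
expression profile (default) or by averaging per-sample normal delta ranks;
the edge-perturbation value is

    Delta[e, s] = delta[e, s] - delta_bar[e]

which measures how far sample s's relative ordering of the pair deviates from
normal.  Because ranks depend only on the within-sample ordering, Delta is
exactly invariant under any strictly increasing per-sample transform of the
expression values.

The feature transform compresses the perturbation magnitude while keeping its
direction: f = sign(Delta) * log2(|Delta| + 1) (``signed_log``, default) or
f = log2(|Delta| + 1) (``abs_log``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import FLOAT_FMT, edge_id
from .data_io import ExpressionMatrix
from .network import InteractionNetwork

Edge = tuple[str, str]


@dataclass
class RankMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    ranks: np.ndarray  # (G, S), fractional ranks 1..G per column


@dataclass
class DeltaRankMatrix:
    edges: list[Edge]
    sample_ids: list[str]
    delta: np.ndarray  # (E, S)


@dataclass
class BenchmarkVector:
    edges: list[Edge]
    delta_bar: np.ndarray  # (E,)


@dataclass
class EdgePerturbationMatrix:
    edges: list[Edge]
    sample_ids: list[str]
    perturbation: np.ndarray  # (E, S)
    cohort: list[str]

    def tumor_mask(self) -> np.ndarray:
        return np.array([c == "tumor" for c in self.cohort])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.perturbation,
            index=[edge_id(e) for e in self.edges],
            columns=self.sample_ids,
        )


@dataclass
class FeatureMatrix:
    edges: list[Edge]
    sample_ids: list[str]
    features: np.ndarray  # (E, S)
    cohort: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.features,
            index=[edge_id(e) for e in self.edges],
            columns=self.sample_ids,
        )

    def subset_edges(self, edges: list[Edge]) -> "FeatureMatrix":
        idx = {e: i for i, e in enumerate(self.edges)}
        rows = [idx[e] for e in edges]
        return FeatureMatrix(list(edges), self.sample_ids, self.features[rows, :], self.cohort)


def rank_transform(expr: ExpressionMatrix) -> RankMatrix:
    """Per-sample ascending fractional ranks (1-based, ties averaged)."""
    ranks = rankdata(expr.values, axis=0, method="average")
    return RankMatrix(list(expr.gene_ids), list(expr.sample_ids), ranks)


def _edge_index(gene_ids: list[str], net: InteractionNetwork) -> tuple[np.ndarray, np.ndarray, list[Edge]]:
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = sorted(n for n in net.nodes if n not in pos)
    if missing:
        raise KeyError(f"network genes missing from matrix: {missing[:10]}")
    edges = list(net.edges)
    i_idx = np.array([pos[a] for a, _ in edges])
    j_idx = np.array([pos[b] for _, b in edges])
    return i_idx, j_idx, edges


def delta_rank(ranks: RankMatrix, net: InteractionNetwork) -> DeltaRankMatrix:
    """delta[e, s] = r[i, s] - r[j, s] for canonical edge (i, j)."""
    i_idx, j_idx, edges = _edge_index(ranks.gene_ids, net)
    delta = ranks.ranks[i_idx, :] - ranks.ranks[j_idx, :]
    return DeltaRankMatrix(edges, list(ranks.sample_ids), delta)


def benchmark_vector(
    normal: ExpressionMatrix, net: InteractionNetwork, method: str = "rank_of_mean"
) -> BenchmarkVector:
    """Normal benchmark delta-rank vector.

    ``rank_of_mean`` (default): rank the per-gene mean normal expression
    profile, then take edge rank differences.  ``mean_of_delta``: average the
    per-sample normal delta ranks.
    """
    if normal.n_samples == 0:
        raise ValueError("normal cohort is empty")
    if method == "rank_of_mean":
        mean_profile = normal.values.mean(axis=1)
        mean_ranks = rankdata(mean_profile, method="average")
        pos = {g: i for i, g in enumerate(normal.gene_ids)}
        missing = sorted(n for n in net.nodes if n not in pos)
        if missing:
            raise KeyError(f"network genes missing from matrix: {missing[:10]}")
        edges = list(net.edges)
        i_idx = np.array([pos[a] for a, _ in edges])
        j_idx = np.array([pos[b] for _, b in edges])
        delta_bar = mean_ranks[i_idx] - mean_ranks[j_idx]
    elif method == "mean_of_delta":
        d = delta_rank(rank_transform(normal), net)
        edges = d.edges
        delta_bar = d.delta.mean(axis=1)
    else:
        raise ValueError("method must be 'rank_of_mean' or 'mean_of_delta'")
    return BenchmarkVector(edges, delta_bar)


def edge_perturbation(
    delta: DeltaRankMatrix, bench: BenchmarkVector, cohort: list[str] | None = None
) -> EdgePerturbationMatrix:
    """Delta[e, s] = delta[e, s] - delta_bar[e]."""
    if delta.edges != bench.edges:
        raise ValueError("edge sets/ordering of delta matrix and benchmark differ")
    pert = delta.delta - bench.delta_bar[:, None]
    if cohort is None:
        cohort = ["tumor"] * len(delta.sample_ids)
    return EdgePerturbationMatrix(list(delta.edges), list(delta.sample_ids), pert, list(cohort))


def compute_epm(
    expr: ExpressionMatrix,
    net: InteractionNetwork,
    benchmark_method: str = "rank_of_mean",
    bench: BenchmarkVector | None = None,
) -> EdgePerturbationMatrix:
    """Full EPM for a combined tumor+normal matrix.

    The benchmark is derived from the matrix's normal samples unless an
    externally computed ``bench`` is supplied (e.g. for a validation cohort
    scored against the training benchmark).
    """
    if bench is None:
        normal_cols = [s for s, c in zip(expr.sample_ids, expr.cohort) if c == "normal"]
        if not normal_cols:
            raise ValueError("no normal samples to derive the benchmark from")
        bench = benchmark_vector(expr.subset_samples(normal_cols), net, benchmark_method)
    d = delta_rank(rank_transform(expr), net)
    return edge_perturbation(d, bench, cohort=expr.cohort)


def feature_transform(epm: EdgePerturbationMatrix, mode: str = "signed_log") -> FeatureMatrix:
    """Log-compress perturbations: sign(Delta)*log2(|Delta|+1) or log2(|Delta|+1)."""
    mag = np.log2(np.abs(epm.perturbation) + 1.0)
    if mode == "signed_log":
        f = np.sign(epm.perturbation) * mag
    elif mode == "abs_log":
        f = mag
    else:
        raise ValueError("mode must be 'signed_log' or 'abs_log'")
    return FeatureMatrix(list(epm.edges), list(epm.sample_ids), f, list(epm.cohort))


def write_edge_matrix(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="edge", float_format=FLOAT_FMT)


def write_benchmark(bench: BenchmarkVector, path) -> None:
    pd.Series(
        bench.delta_bar, index=[edge_id(e) for e in bench.edges], name="delta_bar"
    ).to_csv(path, sep="\t", index_label="edge", float_format=FLOAT_FMT)
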