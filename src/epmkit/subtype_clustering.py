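"""Consensus clustering of tumor samples on characteristic-edge features.

Repeated PAM (partitioning around medoids) on Spearman distance over
resampled sample subsets; pairwise co-clustering frequencies form the
consensus matrix per k.  k is chosen by the relative change in area under the
consensus CDF, and final labels come from average-linkage hierarchical
clustering of the consensus dissimilarity.  Cluster reproducibility on an
independent cohort is scored by the in-group proportion (IGP): the fraction
of validation samples, assigned to training centroids, whose nearest
validation neighbour shares their cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr

from ._util import derive_seed
from .epm import FeatureMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- distances

def spearman_distance(x: np.ndarray, y: np.ndarray) -> float:
    """d = 1 - Spearman rho; a constant vector gets rho = 0 (d = 1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant vector in spearman_distance; rho set to 0")
        return 1.0
    rho = spearmanr(x, y).statistic
    return float(1.0 - rho)


def spearman_distance_matrix(columns: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman rho between the columns of ``columns``."""
    ranks = rankdata(columns, axis=0, method="average")
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant columns in spearman distance; rho set to 0", constant.sum())
    centered = ranks - ranks.mean(axis=0)
    denom = np.where(constant, 1.0, np.sqrt((centered**2).sum(axis=0)))
    normed = centered / denom
    rho = normed.T @ normed
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------- PAM

def pam(dist: np.ndarray, k: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """k-medoids with BUILD initialisation and best-improvement SWAP.

    Deterministic: ties are broken by the lowest point index, so ``seed`` is
    accepted for interface symmetry but unused.  Returns (labels, medoids)
    with labels in 0..k-1 following medoid order.
    """
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    if k <= 0 or k > n:
        raise ValueError(f"need 0 < k <= n (k={k}, n={n})")
    if k == n:
        medoids = np.arange(n)
        return np.arange(n), medoids

    # small instances: exact enumeration (SWAP's single-exchange neighbourhood
    # can miss optima that differ in two medoids at once)
    if k == 2 and n <= 200:
        pair_cost = np.minimum(dist[:, :, None], dist[:, None, :]).sum(axis=0)
        iu = np.triu_indices(n, k=1)
        flat = np.argmin(pair_cost[iu])
        medoids = np.array([iu[0][flat], iu[1][flat]])
        return np.argmin(dist[:, medoids], axis=1), medoids
    if math.comb(n, k) <= 2000:
        import itertools

        best = min(
            (float(dist[:, c].min(axis=1).sum()), c)
            for c in itertools.combinations(range(n), k)
        )
        medoids = np.array(best[1])
        return np.argmin(dist[:, medoids], axis=1), medoids

    # BUILD: greedy cost-reduction insertion
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        reduction = np.maximum(nearest[:, None] - dist, 0.0).sum(axis=0)
        reduction[medoids] = -np.inf
        h = int(np.argmax(reduction))
        medoids.append(h)
        nearest = np.minimum(nearest, dist[:, h])

    # SWAP: best-improvement until no swap lowers the total cost
    medoids = np.array(medoids)
    while True:
        d_med = dist[:, medoids]  # (n, k)
        order = np.argsort(d_med, axis=1)
        nearest_idx = order[:, 0]
        nearest_d = d_med[np.arange(n), nearest_idx]
        second_d = d_med[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        cost = nearest_d.sum()
        best = (0.0, None)
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            base = np.where(nearest_idx == mi, second_d, nearest_d)
            for h in non_medoids:
                new_cost = np.minimum(base, dist[:, h]).sum()
                gain = cost - new_cost
                if gain > best[0] + 1e-12:
                    best = (gain, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h

    d_med = dist[:, medoids]
    labels = np.argmin(d_med, axis=1)
    return labels, medoids


def pam_cost(dist: np.ndarray, medoids: np.ndarray) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


# -------------------------------------------------------------- consensus

@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    labels: np.ndarray  # per-sample cluster id, 1..chosen_k
    sample_ids: list[str] = field(default_factory=list)


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    xs, counts = np.unique(vals, return_counts=True)
    cdf = np.cumsum(counts) / vals.size
    if xs.size < 2:
        return float(xs[0]) if xs.size else 0.0
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def consensus_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    """Final labels: average-linkage hierarchical clustering of 1 - consensus."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    z = linkage(squareform(d, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(
    features: FeatureMatrix,
    k_range: list[int] | range = range(2, 7),
    reps: int = 100,
    p_item: float = 0.8,
    seed: int = 0,
    chosen_k: int | None = None,
) -> ConsensusResult:
    """Resampled PAM consensus clustering of samples (columns of ``features``).

    Per repetition, ceil(p_item * n) samples are drawn without replacement and
    clustered by PAM on Spearman distance; co-clustering counts over
    co-sampling counts give the consensus matrix.  ``chosen_k`` overrides the
    delta-area criterion when supplied.
    """
    x = features.features
    n = x.shape[1]
    if n < 10:
        raise ValueError("need at least 10 samples for consensus clustering")
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    k_range = list(k_range)
    dist_full = spearman_distance_matrix(x)
    n_sub = math.ceil(p_item * n)

    consensus: dict[int, np.ndarray] = {}
    for k in k_range:
        hits = np.zeros((n, n))
        tries = np.zeros((n, n))
        for r in range(reps):
            rng = np.random.default_rng(derive_seed(seed, f"consensus:{k}:{r}"))
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            sub = dist_full[np.ix_(idx, idx)]
            labels, _ = pam(sub, k)
            tries[np.ix_(idx, idx)] += 1.0
            same = labels[:, None] == labels[None, :]
            hits[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            c = hits / tries
        never = ~np.isfinite(c)
        np.fill_diagonal(never, False)
        if never.any():
            fill = np.nanmean(np.where(np.isfinite(c), c, np.nan))
            log.warning("%d sample pairs never co-sampled; imputing mean consensus", never.sum() // 2)
            c[never] = fill
        np.fill_diagonal(c, 1.0)
        consensus[k] = c

    area = {k: _cdf_area(consensus[k]) for k in k_range}
    delta_area: dict[int, float] = {}
    prev = None
    for k in k_range:
        if prev is None or area[prev] == 0:
            delta_area[k] = area[k]
        else:
            delta_area[k] = (area[k] - area[prev]) / area[prev]
        prev = k
    if chosen_k is None:
        chosen_k = max(k_range, key=lambda k: (delta_area[k], -k))
    labels = consensus_labels(consensus[chosen_k], chosen_k)
    return ConsensusResult(
        k_range=k_range,
        consensus=consensus,
        area=area,
        delta_area=delta_area,
        chosen_k=int(chosen_k),
        labels=labels,
        sample_ids=list(features.sample_ids),
    )


# --------------------------------------------------------------------- IGP

@dataclass
class IGPResult:
    igp: dict[int, float]  # cluster id -> in-group proportion (nan if undefined)
    assignment: np.ndarray  # per-validation-sample cluster id


def _pairwise_distance(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """Distance between columns of a (m cols) and columns of b (p cols)."""
    if metric == "spearman":
        joint = spearman_distance_matrix(np.hstack([a, b]))
        return joint[: a.shape[1], a.shape[1]:]
    if metric == "euclidean":
        diff = a[:, :, None] - b[:, None, :]
        return np.sqrt((diff**2).sum(axis=0))
    raise ValueError("metric must be 'spearman' or 'euclidean'")


def igp_validate(
    train_features: FeatureMatrix,
    train_labels: np.ndarray,
    valid_features: FeatureMatrix,
    metric: str = "spearman",
) -> IGPResult:
    """In-group proportion of training clusters on a validation cohort.

    Validation samples are assigned to the nearest training-cluster centroid
    (mean feature vector); a cluster's IGP is the fraction of its assigned
    validation samples whose nearest validation neighbour (excluding self) is
    assigned to the same cluster.
    """
    if train_features.edges != valid_features.edges:
        raise ValueError("training and validation cohorts must share the edge set")
    train_labels = np.asarray(train_labels)
    clusters = sorted(set(int(c) for c in train_labels))
    centroids = np.column_stack(
        [train_features.features[:, train_labels == c].mean(axis=1) for c in clusters]
    )
    xv = valid_features.features
    d_cent = _pairwise_distance(xv, centroids, metric)  # (n_valid, n_clusters)
    assignment = np.array([clusters[i] for i in np.argmin(d_cent, axis=1)])

    d_vv = _pairwise_distance(xv, xv, metric)
    np.fill_diagonal(d_vv, np.inf)
    nn = np.argmin(d_vv, axis=1)
    igp: dict[int, float] = {}
    for c in clusters:
        members = np.where(assignment == c)[0]
        if members.size == 0 or xv.shape[1] < 2:
            igp[c] = float("nan")
            continue
        igp[c] = float(np.mean(assignment[nn[members]] == c))
    return IGPResult(igp=igp, assignment=assignment)
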