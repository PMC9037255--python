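"""Subtype-specific characteristic edge clusters.

Characteristic-edge features are z-scored per edge across all samples,
hierarchically clustered (complete linkage) and cut into a fixed number of
clusters; small clusters are dropped.  For each surviving cluster and each
subtype, the fraction of member edges whose |within-subtype mean z| exceeds
``mean_cut`` is computed; a cluster is characteristic for a subtype when that
fraction exceeds ``pct_cut``.  Gene lists (union of member-edge endpoints) of
characteristic clusters are exported for external pathway-enrichment tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from ._util import edge_id
from .epm import Edge, FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class EdgeClusterReport:
    cluster_id: int
    member_edges: list[Edge]
    percentage: dict[int, float]  # subtype -> fraction of edges with |mean z| > mean_cut
    characteristic_for: list[int]
    gene_list: list[str]


def zscore_edges(features: FeatureMatrix) -> np.ndarray:
    """Per-edge z-score across all samples (sample sd, ddof=1).

    Zero-variance edges become all-zero rows.
    """
    x = features.features
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero_var = sd[:, 0] == 0
    if zero_var.any():
        log.info("%d zero-variance edges z-scored to 0", int(zero_var.sum()))
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd
    z[zero_var, :] = 0.0
    return z


def find_characteristic_clusters(
    z: np.ndarray,
    edges: list[Edge],
    labels: np.ndarray,
    n_clusters: int = 100,
    min_size: int = 30,
    mean_cut: float = 0.5,
    pct_cut: float = 0.7,
    distance: str = "euclidean",
) -> list[EdgeClusterReport]:
    """Complete-linkage clustering of edge z-profiles and the 0.5/0.7 rules.

    ``labels`` assigns each sample (column of ``z``) to a subtype.  Returns a
    report per surviving cluster, ordered by cluster id.
    """
    labels = np.asarray(labels)
    if z.shape[1] != labels.size:
        raise ValueError("labels must cover all samples")
    if n_clusters >= len(edges):
        raise ValueError("n_clusters must be smaller than the number of edges")
    if distance == "euclidean":
        lk = linkage(z, method="complete", metric="euclidean")
    elif distance == "correlation":
        lk = linkage(z, method="complete", metric="correlation")
    else:
        raise ValueError("distance must be 'euclidean' or 'correlation'")
    edge_cluster = fcluster(lk, t=n_clusters, criterion="maxclust")

    subtypes = sorted(set(int(s) for s in labels))
    sub_means = {s: z[:, labels == s].mean(axis=1) for s in subtypes}

    reports: list[EdgeClusterReport] = []
    survivors = 0
    for cid in sorted(set(edge_cluster)):
        members = np.where(edge_cluster == cid)[0]
        if members.size < min_size:
            continue
        survivors += 1
        pct = {
            s: float(np.mean(np.abs(sub_means[s][members]) > mean_cut)) for s in subtypes
        }
        char_for = [s for s in subtypes if pct[s] > pct_cut]
        member_edges = [edges[i] for i in members]
        genes = sorted({g for e in member_edges for g in e})
        reports.append(
            EdgeClusterReport(
                cluster_id=int(cid),
                member_edges=member_edges,
                percentage=pct,
                characteristic_for=char_for,
                gene_list=genes,
            )
        )
    if survivors == 0:
        log.warning("no edge cluster reaches min_size=%d; empty report", min_size)
    return reports


def write_gene_lists(reports: list[EdgeClusterReport], out_dir) -> None:
    """One gene-per-line file per characteristic cluster, plus a GMT file."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gmt_lines = []
    for rep in reports:
        if not rep.characteristic_for:
            continue
        name = f"cluster{rep.cluster_id}_subtype{'_'.join(map(str, rep.characteristic_for))}"
        (out_dir / f"{name}.genes.txt").write_text("\n".join(rep.gene_list) + "\n")
        gmt_lines.append("\t".join([name, "characteristic_cluster"] + rep.gene_list))
    (out_dir / "characteristic_clusters.gmt").write_text("\n".join(gmt_lines) + "\n" if gmt_lines else "")


def report_table(reports: list[EdgeClusterReport]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for rep in reports:
        row = {
            "cluster_id": rep.cluster_id,
            "n_edges": len(rep.member_edges),
            "characteristic_for": ",".join(map(str, rep.characteristic_for)),
            "edges": ";".join(edge_id(e) for e in rep.member_edges),
        }
        for s, p in rep.percentage.items():
            row[f"pct_subtype{s}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def hypergeometric_enrichment(
    gene_list: list[str], gmt_path, background: list[str]
) -> "pd.DataFrame":
    """Convenience hypergeometric enrichment against a user-supplied GMT file."""
    import pandas as pd
    from scipy.stats import hypergeom

    from .differential import bh_adjust

    bg = set(background)
    query = set(gene_list) & bg
    rows = []
    with open(gmt_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, members = parts[0], set(parts[2:]) & bg
            if not members:
                continue
            k = len(query & members)
            p = hypergeom.sf(k - 1, len(bg), len(members), len(query))
            rows.append({"set": name, "overlap": k, "set_size": len(members), "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df
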