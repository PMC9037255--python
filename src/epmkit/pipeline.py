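"""End-to-end pipeline: data_io -> network -> EPM -> feature selection ->
consensus subtyping -> characteristic clusters -> differential screen ->
risk model, with a JSON run manifest (config hash, per-stage file checksums,
warnings) and deterministic, fixed-precision outputs."""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import characteristic_clusters as cc
from . import data_io, differential, epm, feature_selection, network, risk_model
from . import subtype_clustering as sc
from ._util import FLOAT_FMT, derive_seed, edge_id, json_dumps_stable, sha256_file
from .config import PipelineConfig, config_hash

log = logging.getLogger(__name__)

STAGES = [
    "data_io",
    "network",
    "epm",
    "feature_selection",
    "subtype_clustering",
    "characteristic_clusters",
    "differential",
    "risk_model",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to out_dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.resume and (out / "manifest.json").exists():
        cached = json.loads((out / "manifest.json").read_text())
        if (
            cached.get("config_hash") == config_hash(cfg)
            and "failed_stage" not in cached
            and all((out / f).exists() for f in cached.get("files", {}))
        ):
            log.info("resume: completed run with matching config found; reusing")
            return cached
    manifest: dict = {
        "config": cfg.model_dump(),
        "config_hash": config_hash(cfg),
        "stages": [],
        "warnings": [],
        "files": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            t0 = _time.perf_counter()
            files = globals()[f"_stage_{stage}"](cfg, out, state, manifest)
            for f in files:
                manifest["files"][str(Path(f).relative_to(out))] = sha256_file(f)
            manifest["stages"].append(
                {"name": stage, "seconds": round(_time.perf_counter() - t0, 3)}
            )
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "stage", stage)
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json_dumps_stable(manifest))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    (out / "manifest.json").write_text(json_dumps_stable(manifest))
    return manifest


# ------------------------------------------------------------------ stages

def _stage_data_io(cfg, out, state, manifest):
    tumor = data_io.read_expression(cfg.tumor_expression, "tumor")
    normal = data_io.read_expression(cfg.normal_expression, "normal")
    mats = [tumor, normal]
    if cfg.validation_tumor_expression:
        mats.append(data_io.read_expression(cfg.validation_tumor_expression, "tumor"))
    if cfg.validation_normal_expression:
        mats.append(data_io.read_expression(cfg.validation_normal_expression, "normal"))
    mats = data_io.filter_zero_genes(mats, cfg.zero_filter_threshold)
    state["tumor"], state["normal"] = mats[0], mats[1]
    state["expr"] = mats[0].concat_samples(mats[1])
    i = 2
    if cfg.validation_tumor_expression:
        state["valid_tumor"] = mats[i]
        i += 1
    if cfg.validation_normal_expression:
        state["valid_normal"] = mats[i]
    state["clinical"] = data_io.read_clinical(cfg.clinical)
    if cfg.validation_clinical:
        state["valid_clinical"] = data_io.read_clinical(cfg.validation_clinical)
    path = out / "expression.filtered.tsv"
    data_io.write_expression(state["expr"], path)
    return [path]


def _stage_network(cfg, out, state, manifest):
    raw = data_io.read_network_edges(cfg.network)
    net = network.build_network(raw)
    net = network.restrict_to_genes(net, state["expr"].gene_ids)
    state["network"] = net
    summary = out / "network.summary.json"
    summary.write_text(net.summary_json())
    edges_path = out / "network.edges.tsv"
    data_io.write_network_edges(list(net.edges), edges_path)
    return [summary, edges_path]


def _stage_epm(cfg, out, state, manifest):
    mat = epm.compute_epm(state["expr"], state["network"], cfg.benchmark)
    feats = epm.feature_transform(mat, cfg.feature_transform)
    state["epm"], state["features"] = mat, feats
    if "valid_tumor" in state:
        vt = state["valid_tumor"]
        vn = state.get("valid_normal")
        vexpr = vt.concat_samples(vn) if vn is not None else vt
        bench = (
            epm.benchmark_vector(vn, state["network"], cfg.benchmark)
            if vn is not None
            else epm.benchmark_vector(
                state["expr"].subset_samples(
                    [s for s, c in zip(state["expr"].sample_ids, state["expr"].cohort) if c == "normal"]
                ),
                state["network"],
                cfg.benchmark,
            )
        )
        vepm = epm.compute_epm(vexpr, state["network"], cfg.benchmark, bench=bench)
        state["valid_features"] = epm.feature_transform(vepm, cfg.feature_transform)
    p1 = out / "epm.tsv"
    p2 = out / "features.tsv"
    epm.write_edge_matrix(mat.to_frame(), p1)
    epm.write_edge_matrix(feats.to_frame(), p2)
    return [p1, p2]


def _stage_feature_selection(cfg, out, state, manifest):
    top_k = cfg.top_k
    n_edges = len(state["epm"].edges)
    if top_k > n_edges:
        manifest["warnings"].append(
            f"top_k={top_k} exceeds edge count {n_edges}; clamped"
        )
        top_k = n_edges
    sel = feature_selection.select_edges(state["epm"], top_k=top_k)
    state["selection"] = sel
    path = out / "edge_selection.tsv"
    feature_selection.write_selection(sel, path)
    return [path]


def _stage_subtype_clustering(cfg, out, state, manifest):
    feats = state["features"].subset_edges(state["selection"].edges)
    tumor_cols = [s for s, c in zip(feats.sample_ids, feats.cohort) if c == "tumor"]
    idx = [feats.sample_ids.index(s) for s in tumor_cols]
    tumor_feats = epm.FeatureMatrix(
        feats.edges, tumor_cols, feats.features[:, idx], ["tumor"] * len(idx)
    )
    state["tumor_features"] = tumor_feats
    res = sc.consensus_cluster(
        tumor_feats,
        k_range=range(cfg.k_min, cfg.k_max + 1),
        reps=cfg.reps,
        p_item=cfg.p_item,
        seed=derive_seed(cfg.seed, "subtype_clustering"),
        chosen_k=cfg.chosen_k,
    )
    state["consensus"] = res
    files = []
    for k, c in res.consensus.items():
        p = out / f"consensus.k{k}.tsv"
        pd.DataFrame(c, index=tumor_cols, columns=tumor_cols).to_csv(
            p, sep="\t", float_format=FLOAT_FMT
        )
        files.append(p)
    labels_path = out / "subtype_labels.tsv"
    pd.DataFrame({"sample": tumor_cols, "cluster": res.labels}).to_csv(
        labels_path, sep="\t", index=False
    )
    files.append(labels_path)

    summary = {
        "chosen_k": res.chosen_k,
        "area": {str(k): v for k, v in res.area.items()},
        "delta_area": {str(k): v for k, v in res.delta_area.items()},
    }
    if "valid_features" in state:
        vfeats = state["valid_features"].subset_edges(state["selection"].edges)
        vt_cols = [s for s, c in zip(vfeats.sample_ids, vfeats.cohort) if c == "tumor"]
        vidx = [vfeats.sample_ids.index(s) for s in vt_cols]
        vmat = epm.FeatureMatrix(
            vfeats.edges, vt_cols, vfeats.features[:, vidx], ["tumor"] * len(vidx)
        )
        igp = sc.igp_validate(tumor_feats, res.labels, vmat)
        state["igp"] = igp
        state["valid_tumor_features"] = vmat
        summary["igp"] = {str(k): v for k, v in igp.igp.items()}
    sj = out / "clustering.summary.json"
    sj.write_text(json_dumps_stable(summary))
    files.append(sj)
    return files


def _stage_characteristic_clusters(cfg, out, state, manifest):
    tf = state["tumor_features"]
    z = cc.zscore_edges(tf)
    n_clusters = cfg.n_clusters
    if n_clusters >= len(tf.edges):
        n_clusters = max(2, len(tf.edges) // 2)
        manifest["warnings"].append(
            f"n_clusters={cfg.n_clusters} >= selected edges {len(tf.edges)}; clamped to {n_clusters}"
        )
    reports = cc.find_characteristic_clusters(
        z,
        tf.edges,
        state["consensus"].labels,
        n_clusters=n_clusters,
        min_size=cfg.min_size,
        mean_cut=cfg.mean_cut,
        pct_cut=cfg.pct_cut,
    )
    state["char_clusters"] = reports
    path = out / "characteristic_clusters.tsv"
    cc.report_table(reports).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    cc.write_gene_lists(reports, out / "gene_lists")
    files = [path] + sorted((out / "gene_lists").glob("*"))
    return files


def _stage_differential(cfg, out, state, manifest):
    tumor = state["tumor"]
    labels = {
        s: f"cluster{c}"
        for s, c in zip(state["tumor_features"].sample_ids, state["consensus"].labels)
    }
    res = differential.two_group_screen(
        tumor.to_frame()[list(labels.keys())],
        labels,
        "cluster1",
        "cluster2",
        lfc_cut=cfg.lfc_cut,
        fdr_cut=cfg.fdr_cut,
        log_transform=True,
    )
    state["deg"] = res
    path = out / "differential_expression.tsv"
    res.write(path)
    files = [path]
    if cfg.methylation:
        beta = pd.read_csv(cfg.methylation, sep="\t", index_col=0)
        beta = differential.preprocess_methylation(beta)
        shared = [s for s in beta.columns if s in labels]
        mres = differential.two_group_screen(
            beta[shared],
            labels,
            "cluster1",
            "cluster2",
            lfc_cut=cfg.meth_lfc_cut,
            fdr_cut=cfg.fdr_cut,
            log_transform=False,
        )
        state["dmp"] = mres
        mpath = out / "differential_methylation.tsv"
        mres.write(mpath)
        files.append(mpath)
    return files


def _stage_risk_model(cfg, out, state, manifest):
    tumor = state["tumor"]
    clinical = state["clinical"].subset(tumor.sample_ids)
    log_expr = np.log2(tumor.to_frame() + 1.0)

    deg_genes = list(state["deg"].passing)
    if len(deg_genes) < 2:
        raise ValueError("fewer than 2 differential genes; cannot build a risk model")
    screen = risk_model.cox_screen(log_expr.loc[deg_genes], clinical, p_cut=cfg.cox_p_cut)
    prognostic = list(screen.index[screen["selected"]])
    if len(prognostic) < 2:
        raise ValueError("fewer than 2 prognostic genes pass univariate Cox")
    model = risk_model.lasso_cox_select(
        log_expr.loc[prognostic],
        clinical,
        n_folds=cfg.n_folds,
        seed=derive_seed(cfg.seed, "lasso_folds"),
        lambda_rule=cfg.lambda_rule,
    )
    scores = risk_model.risk_score(model, log_expr)
    cut = risk_model.optimal_cutpoint(scores.to_numpy(), clinical, minprop=cfg.minprop)
    model.cutpoint = cut.cutpoint
    groups = np.where(cut.high, "high", "low")
    ev = risk_model.km_logrank(groups, clinical)
    ev.auc_at = risk_model.time_dependent_auc(scores.to_numpy(), clinical, cfg.horizons)
    state["risk_model"], state["risk_eval"] = model, ev

    files = []
    p = out / "risk_model.json"
    p.write_text(model.to_json())
    files.append(p)
    p = out / "cox_screen.tsv"
    screen.to_csv(p, sep="\t", float_format=FLOAT_FMT)
    files.append(p)
    p = out / "risk_scores.tsv"
    pd.DataFrame({"sample": scores.index, "score": scores.to_numpy(), "group": groups}).to_csv(
        p, sep="\t", index=False, float_format=FLOAT_FMT
    )
    files.append(p)
    p = out / "risk_evaluation.json"
    p.write_text(ev.to_json())
    files.append(p)
    for name, curve in ev.km_curves.items():
        cp = out / f"km_{name}.tsv"
        curve.to_csv(cp, sep="\t", index=False, float_format=FLOAT_FMT)
        files.append(cp)

    if "valid_tumor" in state and "valid_clinical" in state:
        vt = state["valid_tumor"]
        vclin = state["valid_clinical"].subset(vt.sample_ids)
        vlog = np.log2(vt.to_frame() + 1.0)
        vscores = risk_model.risk_score(model, vlog)
        vhigh = vscores.to_numpy() > model.cutpoint
        vgroups = np.where(vhigh, "high", "low")
        vev = risk_model.km_logrank(vgroups, vclin)
        vev.auc_at = risk_model.time_dependent_auc(
            vscores.to_numpy(), vclin, cfg.horizons, train_clinical=clinical
        )
        state["valid_risk_eval"] = vev
        p = out / "risk_evaluation.validation.json"
        p.write_text(vev.to_json())
        files.append(p)
    return files
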