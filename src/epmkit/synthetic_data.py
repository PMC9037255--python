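"""Synthetic cohorts with the statistical structure the EPM analysis assumes.

The generator emulates the study design end to end: a background interaction
network; normal samples whose gene ranks are stable around a baseline
profile; tumor samples in two latent subtypes, each of which inverts the
expression ordering of its own module of gene pairs; survival times following
a proportional-hazards model driven by subtype and a small set of prognostic
genes; independent uniform right-censoring; and an optional methylation
matrix with planted differential sites.

Module edges are realised as isolated interacting pairs (their endpoint genes
carry no other edges), so the ground-truth perturbed-edge set is exact: a
mean shift on a gene perturbs every edge it touches, and tying the modules to
pendant pairs keeps truth unambiguous.  Rank inversion is produced by
swapping the two endpoint baseline means, interpolated by ``effect_size``
(1 = full swap), rather than by permuting ranks directly, so tumor matrices
remain valid expression data.

All randomness flows from one root seed through named substreams, so every
output is bitwise reproducible from (params, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._util import rng_for
from .data_io import ClinicalTable, ExpressionMatrix
from .network import InteractionNetwork, build_network
from .epm import Edge


@dataclass(frozen=True)
class CohortParams:
    """Generative settings; defaults are the desk-scale study conditions."""

    n_genes: int = 600
    n_edges: int = 2000
    n_tumor_per_subtype: int = 60
    n_normal: int = 40
    module_n_edges: int = 40        # planted perturbed pairs per subtype
    effect_size: float = 1.0        # 0 = no perturbation, 1 = full mean swap
    module_min_gap: float = 2.0     # min log2-mean gap within a module pair
    mu_low: float = 1.0             # baseline log2-mean range
    mu_high: float = 9.0
    sigma_within: float = 0.3       # within-sample log2 noise
    n_prognostic: int = 8
    gamma: float = 0.6              # |hazard coefficient| per prognostic gene
    prognostic_sd: float = 1.0      # per-sample latent log2 sd of prognostic genes
    prognostic_subtype_shift: float = 1.0
    n_de_genes: int = 12            # extra subtype-programme genes (half per subtype)
    de_shift: float = 1.2           # log2 shift of DE genes in their subtype
    subtype_beta: float = 0.7      # log hazard ratio of subtype 2 vs 1
    baseline_median_days: float = 730.0
    censoring: float = 0.3          # target censored fraction


@dataclass
class SyntheticTruth:
    subtype: dict[str, int]                 # tumor sample -> {1, 2}
    perturbed_edges: dict[int, list[Edge]]  # subtype -> planted edge module
    prognostic_genes: dict[str, float]      # gene -> hazard coefficient gamma
    subtype_hazard: float
    de_genes: list[str]
    generator_params: dict
    seed: int


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # tumor + normal, cohort-labelled
    clinical: ClinicalTable       # tumor samples only
    network: InteractionNetwork   # background graph + module pairs
    truth: SyntheticTruth


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(n_genes: int, n_edges: int, seed: int) -> InteractionNetwork:
    """Preferential-attachment graph: a random-attachment tree backbone plus
    degree-weighted extra edges.  Connected (100% giant component) whenever
    n_edges >= n_genes - 1."""
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds the complete graph ({max_edges})")
    if n_edges < 1 or n_genes < 2:
        raise ValueError("need at least 2 genes and 1 edge")
    rng = rng_for(seed, "network")
    genes = _gene_ids(n_genes)
    degree = np.zeros(n_genes)
    edges: set[tuple[int, int]] = set()

    n_tree_nodes = min(n_genes, n_edges + 1)
    degree[0] = degree[1] = 1
    edges.add((0, 1))
    for v in range(2, n_tree_nodes):
        probs = degree[:v] / degree[:v].sum()
        u = int(rng.choice(v, p=probs))
        edges.add((min(u, v), max(u, v)))
        degree[u] += 1
        degree[v] += 1

    attempts = 0
    while len(edges) < n_edges:
        attempts += 1
        if attempts > 50 * n_edges:
            # dense regime: fall back to uniform sampling of missing pairs
            missing = [
                (i, j)
                for i in range(n_genes)
                for j in range(i + 1, n_genes)
                if (i, j) not in edges
            ]
            take = rng.choice(len(missing), size=n_edges - len(edges), replace=False)
            for t in sorted(take):
                i, j = missing[t]
                edges.add((i, j))
                degree[i] += 1
                degree[j] += 1
            break
        probs = degree / degree.sum()
        a, b = rng.choice(n_genes, size=2, p=probs)
        if a == b:
            continue
        e = (min(a, b), max(a, b))
        if e in edges:
            continue
        edges.add(e)
        degree[a] += 1
        degree[b] += 1
    return build_network([(genes[i], genes[j]) for i, j in sorted(edges)])


def _structure(params: CohortParams, seed: int):
    """Draw everything shared between training and validation cohorts."""
    p = params
    n_module_genes = 2 * 2 * p.module_n_edges
    n_special = n_module_genes + p.n_prognostic + p.n_de_genes
    if n_special >= p.n_genes:
        raise ValueError("n_genes too small for the requested planted structure")
    genes = _gene_ids(p.n_genes)
    rng = rng_for(seed, "structure")
    perm = rng.permutation(p.n_genes)
    module_gene_idx = perm[:n_module_genes]

    # background network on the non-module genes
    bg_idx = np.sort(perm[n_module_genes:])
    bg_genes = [genes[int(i)] for i in bg_idx]
    n_bg_edges = p.n_edges - 2 * p.module_n_edges
    bg_net = generate_network(len(bg_genes), n_bg_edges, seed)
    rename = dict(zip(_gene_ids(len(bg_genes)), bg_genes))
    edge_list = [(rename[a], rename[b]) for a, b in bg_net.edges]

    # subtype-programme (DE) and prognostic genes are taken from the
    # lowest-degree background nodes, so the planted perturbation stays
    # concentrated on the module edges rather than on incident bystanders
    idx_of = {g: int(i) for g, i in zip(genes, range(p.n_genes))}
    inv = {v: k for k, v in rename.items()}
    bg_by_degree = sorted(bg_genes, key=lambda g: (bg_net.degree.get(inv[g], 0), g))
    special = bg_by_degree[: p.n_de_genes + p.n_prognostic]
    rng.shuffle(special)
    de_genes = special[: p.n_de_genes]
    prog_genes = special[p.n_de_genes:]
    half = p.n_de_genes // 2
    de_idx_by_subtype = {
        1: np.array([idx_of[g] for g in de_genes[:half]], dtype=int),
        2: np.array([idx_of[g] for g in de_genes[half:]], dtype=int),
    }
    prog_idx = np.array([idx_of[g] for g in prog_genes], dtype=int)

    # baseline means; module pairs get a guaranteed gap, oriented so the
    # canonical (lexicographically smaller) gene has the smaller mean and
    # every module edge flips in the same direction
    mu = rng.uniform(p.mu_low, p.mu_high, size=p.n_genes)
    modules: dict[int, list[tuple[int, int]]] = {1: [], 2: []}
    pos = 0
    for k in (1, 2):
        for _ in range(p.module_n_edges):
            i, j = int(module_gene_idx[pos]), int(module_gene_idx[pos + 1])
            pos += 2
            if abs(mu[i] - mu[j]) < p.module_min_gap:
                lo, hi = sorted((i, j), key=lambda g: mu[g])
                mu[hi] = mu[lo] + p.module_min_gap + rng.uniform(0, 1)
            if (genes[i] < genes[j]) != (mu[i] < mu[j]):
                mu[i], mu[j] = mu[j], mu[i]
            modules[k].append((i, j))

    module_edges: dict[int, list[Edge]] = {}
    for k in (1, 2):
        mes = []
        for i, j in modules[k]:
            a, b = genes[i], genes[j]
            mes.append((a, b) if a <= b else (b, a))
        module_edges[k] = sorted(mes)
        edge_list.extend(module_edges[k])
    net = build_network(edge_list)

    gammas = np.array([p.gamma * (1 if g % 2 == 0 else -1) for g in range(p.n_prognostic)])
    return {
        "genes": genes,
        "mu": mu,
        "modules": modules,
        "module_edges": module_edges,
        "prog_idx": prog_idx,
        "de_idx_by_subtype": de_idx_by_subtype,
        "gammas": gammas,
        "network": net,
    }

def generate_cohort(
    params: CohortParams = CohortParams(),
    seed: int = 17,
    cohort_name: str = "train",
    _structure_cache: dict | None = None,
) -> SyntheticCohort:
    """One full cohort (tumor + normal expression, clinical table, truth).

    The structural draw (network, modules, baselines, prognostic genes)
    depends only on (params, seed); sample-level noise additionally depends on
    ``cohort_name``, so a validation cohort shares the truth but not the
    samples.
    """
    p = params
    if p.effect_size < 0:
        raise ValueError("effect size must be >= 0")
    if p.n_normal < 5 or p.n_tumor_per_subtype < 10:
        raise ValueError("need n_normal >= 5 and n_tumor_per_subtype >= 10")
    s = _structure_cache if _structure_cache is not None else _structure(p, seed)
    genes, mu = s["genes"], s["mu"]
    n_tumor = 2 * p.n_tumor_per_subtype
    subtype = np.array([1] * p.n_tumor_per_subtype + [2] * p.n_tumor_per_subtype)

    rng_expr = rng_for(seed, f"{cohort_name}:expression")
    # subtype-specific mean profiles: swap module-pair means at effect_size
    mean_by_subtype = {}
    for k in (1, 2):
        mk = mu.copy()
        for i, j in s["modules"][k]:
            mk[i] = mu[i] + p.effect_size * (mu[j] - mu[i])
            mk[j] = mu[j] + p.effect_size * (mu[i] - mu[j])
        # effect_size scales every tumor-specific mean structure, so that at
        # effect 0 tumors are drawn from the normal-tissue distribution
        mk[s["de_idx_by_subtype"][k]] += p.de_shift * p.effect_size
        if k == 2:
            mk[s["prog_idx"]] += p.prognostic_subtype_shift * p.effect_size
        mean_by_subtype[k] = mk

    log_tumor = np.empty((p.n_genes, n_tumor))
    for c in range(n_tumor):
        log_tumor[:, c] = mean_by_subtype[subtype[c]] + rng_expr.normal(
            0, p.sigma_within, size=p.n_genes
        )
    # latent prognostic variation on top of the subtype shift
    eta = rng_expr.normal(
        0, p.prognostic_sd * min(p.effect_size, 1.0), size=(p.n_prognostic, n_tumor)
    )
    log_tumor[s["prog_idx"], :] += eta

    log_normal = mu[:, None] + rng_expr.normal(0, p.sigma_within, size=(p.n_genes, p.n_normal))

    tumor_ids = [f"{cohort_name}_T{c + 1:03d}" for c in range(n_tumor)]
    normal_ids = [f"{cohort_name}_N{c + 1:03d}" for c in range(p.n_normal)]
    expr = ExpressionMatrix(
        gene_ids=list(genes),
        sample_ids=tumor_ids + normal_ids,
        values=np.hstack([2.0**log_tumor, 2.0**log_normal]),
        cohort=["tumor"] * n_tumor + ["normal"] * p.n_normal,
    )

    # proportional-hazards survival on tumor samples
    rng_surv = rng_for(seed, f"{cohort_name}:survival")
    z = log_tumor[s["prog_idx"], :]
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    lp = p.subtype_beta * (subtype == 2) + s["gammas"] @ z
    lam0 = np.log(2.0) / p.baseline_median_days
    t_event = rng_surv.exponential(1.0, size=n_tumor) / (lam0 * np.exp(lp))

    rng_cens = rng_for(seed, f"{cohort_name}:censoring")
    u = rng_cens.uniform(size=n_tumor)
    c_max = _calibrate_censoring(t_event, u, p.censoring)
    c_times = np.maximum(u * c_max, 1e-6)
    event = (t_event <= c_times).astype(int)
    time = np.minimum(t_event, c_times)
    clinical = ClinicalTable(tumor_ids, time, event)

    truth = SyntheticTruth(
        subtype={sid: int(k) for sid, k in zip(tumor_ids, subtype)},
        perturbed_edges={k: list(v) for k, v in s["module_edges"].items()},
        prognostic_genes={
            genes[int(i)]: float(g) for i, g in zip(s["prog_idx"], s["gammas"])
        },
        subtype_hazard=p.subtype_beta,
        de_genes=[
            genes[int(i)]
            for k in (1, 2)
            for i in np.sort(s["de_idx_by_subtype"][k])
        ],
        generator_params=asdict(p),
        seed=seed,
    )
    return SyntheticCohort(expr, clinical, s["network"], truth)


def _calibrate_censoring(t_event: np.ndarray, u: np.ndarray, target: float) -> float:
    """Choose the uniform-censoring upper bound so the realised censored
    fraction is as close as possible to ``target`` (monotone bisection)."""
    if target <= 0:
        return float(t_event.max() / u.min() * 10)

    def frac_censored(c_max):
        return float(np.mean(u * c_max < t_event))

    lo, hi = 1e-3, float(10 * t_event.max() / max(u.min(), 1e-6))
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_study(
    params: CohortParams = CohortParams(), seed: int = 17
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """A training cohort and an independent validation cohort drawn from the
    same generative process (shared structure, fresh samples)."""
    s = _structure(params, seed)
    train = generate_cohort(params, seed, "train", _structure_cache=s)
    valid = generate_cohort(params, seed, "valid", _structure_cache=s)
    return train, valid


@dataclass(frozen=True)
class MethylationParams:
    n_sites: int = 500
    n_planted: int = 50
    delta: float = 0.3       # beta-value shift of planted sites in subtype 2
    noise_sd: float = 0.08
    missing_rate: float = 0.05


def generate_methylation(
    truth: SyntheticTruth,
    params: MethylationParams = MethylationParams(),
    seed: int = 17,
) -> tuple[pd.DataFrame, list[str]]:
    """Beta-value matrix (sites x tumor samples) with planted subtype-
    differential sites; returns (matrix, planted site ids)."""
    p = params
    if not 0 <= p.delta <= 1:
        raise ValueError("delta must lie in [0, 1]")
    samples = list(truth.subtype.keys())
    sub2 = np.array([truth.subtype[s] == 2 for s in samples])
    rng = rng_for(seed, "methylation")
    sites = [f"cg{i:06d}" for i in range(1, p.n_sites + 1)]
    base = rng.uniform(0.15, 0.85, size=p.n_sites)
    beta = base[:, None] + rng.normal(0, p.noise_sd, size=(p.n_sites, len(samples)))
    planted = sorted(rng.choice(p.n_sites, size=p.n_planted, replace=False).tolist())
    for i in planted:
        direction = 1.0 if base[i] < 0.5 else -1.0
        beta[i, sub2] += direction * p.delta
    beta = np.clip(beta, 0.0, 1.0)
    mask = rng.uniform(size=beta.shape) < p.missing_rate
    beta[mask] = np.nan
    df = pd.DataFrame(beta, index=sites, columns=samples)
    return df, [sites[i] for i in planted]
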