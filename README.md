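# epmkit — edge-perturbation subtyping of bulk tumor cohorts

`epmkit` identifies tumor subtypes from *how samples scramble the rank
order of interacting gene pairs*, rather than from absolute expression.
It is aimed at computational biologists analysing bulk expression cohorts
(tumor + normal) who want a rank-based, normalisation-robust alternative
to expression clustering, plus a prognosis model on top.

## The model

For each sample `s`, genes are ranked by expression within the sample.
For each edge `e = (i, j)` of a background gene-interaction network:

```
δ(e, s) = r(i, s) − r(j, s)                    delta rank
Δ(e, s) = δ(e, s) − δ̄(e)                       edge perturbation
f(e, s) = sign(Δ) · log2(|Δ| + 1)              compressed feature
```

where `δ̄` is the delta rank of the mean normal expression profile. The
edges × samples matrix Δ (the **edge-perturbation matrix**, EPM) is exactly
invariant to any strictly increasing per-sample transform of expression.
The pipeline then:

1. selects **characteristic edges** — the intersection of the top-K
   Kruskal–Wallis (tumor vs normal) and top-K tumor-SD edges;
2. finds subtypes by **consensus clustering** (resampled PAM on Spearman
   distance, 100 repetitions, k by the change in area under the consensus
   CDF) and validates them on an independent cohort via the **in-group
   proportion** (IGP);
3. reports **characteristic edge clusters** (complete linkage; clusters ≥ 30
   edges in which > 70% of edges have |within-subtype mean z| > 0.5) and
   exports their gene lists;
4. screens genes differentially between subtypes (Welch t, |logFC| > 0.585,
   BH FDR < 0.01; methylation at |Δβ| > 0.1), then builds a prognosis model:
   univariate Cox (p < 0.01) → LASSO-Cox (CV partial likelihood) →
   `RiskScore = Σ expression × coef` → maximally selected log-rank cutpoint
   → KM/log-rank and time-dependent AUC at 1/3/5 years.

A fully seeded synthetic-study generator (`epmkit.synthetic_data`) produces
cohorts with planted subtype edge modules, prognostic genes, survival and an
independent validation cohort, so the whole pipeline is testable offline.

## Worked example

```bash
# simulate a study: expression, clinical, network, truth
epm simulate --preset default --seed 7 --out sim/

cat > config.yaml <<EOF
tumor_expression: sim/train.tumor.tsv
normal_expression: sim/train.normal.tsv
network: sim/network.tsv
clinical: sim/train.clinical.tsv
validation_tumor_expression: sim/valid.tumor.tsv
validation_normal_expression: sim/valid.normal.tsv
validation_clinical: sim/valid.clinical.tsv
out_dir: out
seed: 7
top_k: 300        # desk-scale analogue of the full-size 30000
n_clusters: 12
min_size: 15
EOF

epm run --config config.yaml
# -> completed 8 stages -> out
```

`out/clustering.summary.json` then contains (numbers from this exact run):

```json
{"chosen_k": 2, "igp": {"1": 1.0, "2": 1.0}, ...}
```

meaning the consensus CDF criterion chose two subtypes and both reproduce
perfectly (IGP = 1.0) on the independent validation cohort.
`out/risk_evaluation.json` reports the risk model on the training cohort:

```json
{
  "auc_at_years": {"1.0": 0.759, "3.0": 0.831, "5.0": 0.903},
  "logrank_chi2": 55.05,
  "logrank_p": 1.18e-13
}
```

high/low risk groups (split at the learned cutpoint in
`out/risk_model.json`) differ strongly in survival, and the score
discriminates 1/3/5-year outcomes well above chance (AUC 0.5). Every
intermediate artifact (EPM, feature matrix, edge selection, consensus
matrices, subtype labels, characteristic clusters and gene lists,
differential tables, risk scores, KM curves) is written to `out/` along
with a manifest of per-file checksums; rerunning the same config gives
byte-identical outputs.

The same stages are available as a library:

```python
from epmkit import (CohortParams, generate_study, compute_epm,
                    feature_transform, select_edges, consensus_cluster)

train, valid = generate_study(CohortParams(), seed=7)
epm = compute_epm(train.expression, train.network)
selection = select_edges(epm, top_k=300)
```

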