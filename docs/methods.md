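# Methods

## The edge-perturbation model

`epmkit` analyses bulk tumor expression through the lens of *gene-pair rank
order* rather than absolute expression. Within each sample `s`, all genes are
ranked by expression (ascending, 1-based, average ties). For every edge
`e = (i, j)` of a background gene-interaction network, stored canonically
with the lexicographically smaller gene first, the delta rank is

    δ[e, s] = r[i, s] − r[j, s].

A normal-tissue benchmark `δ̄[e]` is built by averaging expression over the
normal cohort, ranking that single mean profile, and taking the same edge
differences. The edge-perturbation matrix (EPM) is

    Δ[e, s] = δ[e, s] − δ̄[e],

the deviation of the sample's pair ordering from normal. Because ranks
depend only on the within-sample ordering, Δ is exactly invariant under any
strictly increasing per-sample transform — normalisation choices that act
monotonically per sample (CPM/TPM scaling, log transforms) cannot change it.
A sample whose expression equals the normal mean profile has Δ ≡ 0, and
|Δ| ≤ 2(G−1) for G genes.

Features are log-compressed as `f = sign(Δ)·log2(|Δ|+1)`. A plain
`log2(Δ+1)` is undefined for Δ ≤ −1; the signed form keeps the direction of
the perturbation while compressing its magnitude, and `f = 0` iff `Δ = 0`.
An absolute-value variant `log2(|Δ|+1)` is available via
`feature_transform(..., mode="abs_log")`.

Two readings of the benchmark are possible ("rank the mean profile" vs
"average the per-sample delta ranks"); both are implemented
(`benchmark: rank_of_mean | mean_of_delta`), with `rank_of_mean` the
default. They coincide when the normal cohort is internally consistent and
differ only through rank nonlinearity.

## Characteristic edges

Edges are ranked twice: by the tie-corrected Kruskal–Wallis H statistic
contrasting tumor vs normal Δ values (with two groups this is monotone in
the Mann–Whitney statistic), and by the standard deviation of Δ across tumor
samples. The selection is the intersection of the two top-K sets
(`top_k`, default 30,000 — the published full-scale setting; clamped to the
edge count with a warning when the network is smaller). Both statistics are
computed on the untransformed Δ. Tie-breaking at the top-K boundary is
deterministic: H descending, then p ascending, then edge id; SD descending,
then edge id.

## Consensus subtyping

Tumor samples are clustered on the selected-edge features by resampled
consensus clustering: in each of `reps` (default 100) repetitions,
`⌈p_item·n⌉` samples (`p_item = 0.8`) are drawn without replacement and
partitioned by PAM (k-medoids) on Spearman distance `1 − ρ`; co-clustering
counts over co-sampling counts give a consensus matrix per k. k is chosen by
the relative change in area under the consensus CDF (the first k in the
range reports its raw area), with a user override. Final labels come from
average-linkage hierarchical clustering of `1 − consensus` at the chosen k —
the convention of the standard consensus-clustering implementation — rather
than a final PAM run.

PAM uses BUILD initialisation and best-improvement SWAP with index-based tie
breaking, so results are fully deterministic; each repetition draws its
subsample from a stream derived from the root seed and the repetition index,
making runs reproducible and order-independent. For small search spaces
(k = 2 with n ≤ 200, or C(n, k) ≤ 2000) the optimal medoid set is found by
direct enumeration instead: the single-exchange SWAP neighbourhood can miss
optima that differ in two medoids at once, and exactness is cheap there.

Cluster reproducibility on an independent cohort is scored by the in-group
proportion (IGP): validation samples are assigned to the nearest training
centroid (mean feature vector, Spearman distance; Euclidean available for
documented test geometry), and a cluster's IGP is the fraction of its
assigned samples whose nearest validation neighbour shares the cluster. IGP
is reported for any cluster with at least one assigned sample; an empty
cluster reports missing.

## Characteristic clusters

Selected-edge features are z-scored per edge across all samples (sample
standard deviation, ddof = 1, so the ±0.5 threshold is well defined;
zero-variance edges become zero rows), then clustered by complete-linkage
hierarchical clustering (Euclidean on z rows; correlation distance
available) and cut into `n_clusters` (default 100) clusters. Clusters
smaller than `min_size` (default 30) are dropped. For each surviving
cluster and each subtype, the fraction of member edges with
|within-subtype mean z| > 0.5 is computed; the cluster is characteristic
for a subtype when the fraction exceeds 0.7. Raising either threshold can
only shrink the characteristic set (monotonicity). With two subtypes the
within-subtype means of a z-scored row are anti-symmetric, so a strongly
subtype-specific cluster is typically flagged for both subtypes; the
direction of its mean z distinguishes which subtype carries the
perturbation. Gene lists (union of member-edge endpoints) are exported as
plain text and GMT for external enrichment tools, with an optional
hypergeometric screen against a user-supplied GMT.

## Differential screening

A generic two-group screen serves both expression (optional `log2(x+1)`,
|logFC| > 0.585, FDR < 0.01) and methylation beta values (|difference| >
0.1 on the same scale). Per feature: Welch t-test; Benjamini–Hochberg
step-up across all tested features; strict threshold inequalities. The
screen deliberately uses Welch's t rather than a moderated (empirical
Bayes) linear model: with the cohort sizes this package targets the
moderation gain is modest, and a hook accepts externally computed
p/logFC tables for exact-parity workflows. Zero-variance features with
equal group means report p = 1 (no evidence), with unequal means p = 0
(deterministic separation). Methylation preprocessing drops sites missing
in more than 70% of samples and sets remaining missing values to 0.

## Risk modelling

*Univariate screen.* Per candidate gene, a one-parameter Cox
proportional-hazards fit by Newton–Raphson on the Breslow partial
likelihood (internally standardised covariate; |β| capped at 10 under
monotone likelihood). The Wald p-value screens genes at p < 0.01; the score
statistic at β = 0 is also exposed — for a binary covariate on tie-free
data it equals the log-rank statistic, which the tests verify to 1e-9.

*LASSO-Cox.* L1-penalised Cox regression (coordinate-descent path via
scikit-survival) on internally standardised features; the penalty is chosen
by 10-fold cross-validated Breslow partial likelihood (`min` rule by
default, `1se` available; the fold split is seeded explicitly).
Coefficients are returned on the input scale, so the risk score is the
paper-style linear predictor `RiskScore = Σ expression × coef`.

*Cutpoint.* The high/low threshold is the maximally selected log-rank
statistic: candidates are observed score values whose split leaves at least
`minprop = 0.1` of samples on each side; the candidate maximising the
standardised statistic wins, ties resolving to the smaller cut; high risk
means score > cut. The selected *group assignment* is invariant under
strictly increasing transforms of the score.

*Evaluation.* Kaplan–Meier curves and the two-group log-rank test
(lifelines), plus cumulative/dynamic time-dependent AUC at 1/3/5 years
(scikit-survival's KM/IPCW-weighted estimator; horizons are years ×
365.25, survival times are days throughout the I/O). On fully observed
data the estimator equals the Mann–Whitney concordance between score and
the event-by-t indicator, verified to 1e-9. Horizons with no cases or no
controls report missing.

Cox ties are handled by Breslow throughout (simplest and consistent with
the score-test identity); with continuous survival times ties have measure
zero, and the synthetic generator produces continuous times.

## Synthetic study design

The generator produces the conditions the analysis assumes, plus ground
truth, so every stage is testable without external downloads. Defaults
(the desk-scale study conditions): 600 genes, 2,000 edges, 60+60 tumors in
two subtypes, 40 normals, 30% censoring.

- **Network** — preferential attachment: a random-attachment tree backbone
  plus degree-weighted extra edges; connected whenever the edge budget
  reaches n−1, giant component ≥ 90% of nodes at default density.
- **Normal samples** — per-gene log2 baselines uniform on [1, 9] with
  within-sample Gaussian noise (sd 0.3), giving a stable but not rigid
  rank ordering.
- **Subtype modules** — each subtype owns 40 planted gene pairs whose
  baseline means are at least 2 log2 units apart; in that subtype's tumors
  the two means are swapped, interpolated by `effect_size` (1 = full swap),
  flipping the pair's delta rank relative to the benchmark. Module pairs
  are realised as isolated edges (their endpoints carry no other
  interaction), because a mean shift on a gene perturbs *every* edge it
  touches: isolating the module endpoints is what makes the ground-truth
  perturbed-edge set exact. Real interactomes do not have this property —
  passing recovery tests here shows the machinery works at the stated
  signal strength, not that module boundaries are sharp in real tumors.
  Module pairs are oriented so every flip has the same canonical sign,
  letting the planted module appear as a single coherent edge cluster.
- **Subtype programmes** — 6 further genes per subtype (chosen among the
  lowest-degree background nodes to limit bystander edges) are shifted by
  1.2 log2 units in their subtype, giving each subtype transcriptional
  structure beyond the module itself.
- **Survival** — exponential times with hazard
  `∝ exp(0.7·1[subtype 2] + Σ γ_g z_g)` over 8 prognostic genes with
  alternating coefficients ±0.6 on standardised log expression; prognostic
  genes carry an extra per-sample latent factor (log2 sd 1.0) and a +1.0
  subtype-2 shift so the pipeline's differential → Cox → LASSO path can
  reach them. Censoring is uniform on [0, C] with C calibrated by
  bisection to the target censored fraction. Note the large total hazard
  variance attenuates *marginal* (univariate) effects — by design, the
  planted signal is comfortably recoverable multivariately but individual
  genes sit near the univariate p = 0.01 boundary, as in real cohorts.
- **Validation cohort** — structural draws (network, modules, baselines,
  prognostic genes) are shared; sample-level noise streams differ, giving
  an independent replicate for IGP and external risk validation.
- **Methylation** — 500 sites with Uniform(0.15, 0.85) baselines, Gaussian
  noise (sd 0.08), 50 planted sites shifted by 0.3 between subtypes
  (direction away from the nearer boundary), 5% missing values, clipped to
  [0, 1].
- `effect_size` scales *every* tumor-specific mean structure, so at 0 the
  tumor cohort is drawn from the normal-tissue distribution exactly.

All randomness flows from one root seed through named substreams
(sha256-derived), so outputs are bitwise reproducible and individual
stages can be re-seeded independently.

What the generator does **not** emulate: RNA-seq count noise
(negative-binomial dispersion, library-size effects), batch structure,
overlapping or nested modules, copy-number or mutational processes.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative assumptions, not performance on
real cohorts.

## Desk-scale parameter analogues

The published full-scale settings (top 30,000 edges of ~170k; 100 edge
clusters with a 30-edge size filter) are the config defaults. The
synthetic study is ~85× smaller in edge count, so its analysis uses scaled
analogues preserving the intent: `top_k = 300` (≈ the same fraction of the
edge universe), `n_clusters = 12`, `min_size = 15`. A 100-way cut of a few
hundred selected edges would leave no cluster above 30 edges. The consensus
repetitions (100), thresholds (0.5/0.7, |logFC| 0.585/0.1, FDR 0.01, Cox
p 0.01) and subsampling proportion (0.8) are kept at full-scale values.

## Numerical and engineering choices

- Floats in TSV/JSON outputs are written at fixed precision (`%.6g`), and
  JSON keys are sorted, so identical configs give byte-identical outputs.
- Duplicate gene rows collapse by mean on read; duplicate sample columns
  are an error.
- The zero-expression filter removes a gene when its zero proportion
  reaches the threshold (inclusive ≥ 0.7) in *any* cohort and keeps all
  cohorts on the common surviving gene set.
- Spearman distance of a constant vector is defined as 1 (ρ set to 0) and
  logged.
- Consensus entries for never-co-sampled pairs (possible only at very low
  `p_item`·reps) are imputed with the mean consensus and logged.
- Pipeline stage seeds derive from the root seed by stable hashing of the
  stage name. `resume: true` reuses a completed output directory when the
  config hash matches; per-stage caching was deliberately omitted since a
  full desk-scale run takes seconds.

## Known limitations

- The EPM is materialised densely (edges × samples); full-size interactome
  × cohort matrices (~170k × 1k) fit in a few GB but are not streamed.
- Welch-t differential screening does not moderate variances; for very
  small groups an external moderated table can be supplied.
- The Cox screen tests one gene at a time; correlated markers attenuate
  marginally (see survival design note above).
- IGP validation assumes the validation cohort shares the selected edge
  set and a comparable benchmark; cross-platform rank distortions are not
  modelled.
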