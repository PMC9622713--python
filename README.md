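# glycoclust

Network-based analysis of anti-carbohydrate antibody (ACA) repertoires in
type 1 diabetes (T1D).

Serum contains IgG antibodies against hundreds of natural glycans. Because
many glycans share substructures, ACA levels measured on a multiplexed
bead array are strongly interdependent and cannot be analyzed one glycan at a
time. This package implements a cluster-based pipeline for such data, aimed at
researchers analyzing glycan-array serology across cohorts:

1. **Graph construction.** Each glycan is a point in sample space; a fuzzy
   k-nearest-neighbor graph (k = 5, cosine metric) is built per cohort. Edge
   weights come from the smooth-kNN calibration: for glycan *i*, with
   ρᵢ the distance to its nearest neighbor and σᵢ solved by bisection so that
   Σⱼ exp(−max(0, dᵢⱼ − ρᵢ)/σᵢ) = log₂(k), the directed membership is
   wᵢⱼ = exp(−max(0, dᵢⱼ − ρᵢ)/σᵢ), symmetrized with the probabilistic
   t-conorm a + b − ab.
2. **Cross-cohort merge.** Edges unique to a cohort are kept as is; shared
   edges are fused with w = w₁ + w₂ − w₁w₂ (the same t-conorm), keeping all
   weights in (0, 1].
3. **Community detection.** Two-phase weighted Louvain maximizing
   Newman–Girvan modularity Q = (1/2m) Σᵢⱼ [wᵢⱼ − γ kᵢkⱼ/2m] δ(cᵢ,cⱼ),
   seeded and deterministic.
4. **Cluster profiles.** Fisher-exact functional-class enrichment per
   (cluster, class) with Benjamini–Hochberg adjustment; per-sample cluster
   levels as the first principal component (FPC) of each cluster's z-scored
   glycans, sign-oriented to track the cluster mean.
5. **Association.** Per cluster: FPC ~ progressor + non-progressor + sex +
   first-degree-relative status + HLA risk + draw age (OLS, control as
   reference); per-glycan univariate models on the same design; Tukey HSD + BH
   for a genotype (G/G, G/A, A/A) effect on one glycan's level.
6. **Discrimination.** Nested logistic models of progressor vs control
   (clinical-only vs clinical + cluster FPCs) compared by likelihood-ratio
   test; Mann–Whitney AUC; permutation q-values (label shuffles, model refit
   per iteration); partial R² per term group; and a glycan-saturation analysis
   (ridge logistic on m random glycans, m = 1…200, out-of-fold AUC).

A synthetic-data generator (`glycoclust.synthetic`) emulates the study design
— two cohorts of 576 and 112 samples sharing 202 glycans in 11 latent
correlated blocks, log-normal MFI, planted disease effects on five blocks, a
bimodal exposure glycan, a genotype-dosed glycan — so the whole pipeline is
testable end to end without access to study data.

## Worked example

```python
from glycoclust import *
from glycoclust.synthetic import SynthSpec

spec = SynthSpec(seed=1)
panel = generate_panel(spec)
aca_a, aca_b, clinical, genotypes, truth = generate_cohorts(spec, panel)

merged = merge_graphs(fuzzy_knn_graph(aca_a), fuzzy_knn_graph(aca_b))
part = louvain(merged, seed=1)
print(part.n_communities, round(part.modularity, 3))
# 11 0.907

scores = cluster_fpc(aca_b, part)
fit_null = fit_status_model(clinical, scores, spec="null")
fit_full = fit_status_model(clinical, scores, spec="full")
print(round(fit_null.auc, 3), round(fit_full.auc, 3))
# 0.58 0.908
stat, df, p = lrt(fit_full, fit_null)
print(df, f"{p:.2e}")
# 11 4.09e-06
```

The merged 5-NN graph of the two synthetic cohorts yields 11 communities at
modularity 0.907 — exactly the planted blocks (adjusted Rand index 1.0
against the generator's truth). Adding the 11 cluster FPC scores to the
clinical covariates raises the apparent AUC for progressor-vs-control
discrimination from 0.58 to 0.91, and the likelihood-ratio test on 11 degrees
of freedom rejects the clinical-only model at p ≈ 4e-6.

The same analysis as a narrative sequence of scripts:

```sh
python analysis/01_simulate_cohorts.py --seed 1 --dir results/analysis
python analysis/02_build_network.py    --seed 1 --dir results/analysis
python analysis/03_profile_clusters.py --dir results/analysis
python analysis/04_fit_associations.py --dir results/analysis
python analysis/05_discriminate.py     --seed 1 --dir results/analysis
```

or as one configured run: `glycoclust run --seed 1 --out results/run`
(subcommands `synth` and `network` expose the individual stages).

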