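# Methods

This note documents the models behind `glycoclust`, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open. Every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Graph construction and merging

Glycans are points whose coordinates are their MFI values across a cohort's
samples; distances use the cosine metric, which is scale-invariant per
glycan, so raw background-subtracted MFI is used by default (a `log1p` option
exists but is less critical than it would be under a Euclidean metric).

Edge weights adopt the fuzzy-simplicial-set construction of topological kNN
methods rather than raw distances: with ρᵢ the distance to the nearest
neighbor (local connectivity 1) and σᵢ solved so the memberships sum to
log₂(k), directed weights are exp(−max(0, d−ρ)/σ), symmetrized by
a + b − ab. This choice is forced by the merge rule: "sum minus product" is
the probabilistic t-conorm, i.e. fuzzy union, and it only maps (0,1] × (0,1]
into (0,1] if the per-cohort weights are already membership strengths. Raw
cosine distances would break that contract.

σ is found by plain bisection with an expanding upper bracket; 64 iterations
shrink the bracket far below the 1e-5 tolerance on the membership sum, so the
solution is effectively exact (the test suite checks agreement with an
independent all-pairs implementation using Brent's method to 1e-9 on the
final weights). Constant glycan columns are rejected by name; k must be
smaller than the number of glycans.

Cohorts are merged pairwise in input order; since the t-conorm is commutative
and associative, the order is irrelevant for shared edges. Every edge carries
a provenance flag (one cohort, both, or single-graph).

## Community detection

Louvain is implemented directly (two phases: seeded greedy local moving on
weighted Newman–Girvan modularity at resolution γ, then aggregation with
self-loops, repeated until the modularity gain of a pass is below 1e-10) so
that pass-level modularity is observable and the algorithm's determinism is
under the package's control. Node visit order is a seeded shuffle; a node
moves only on strict gain, with ties among candidate communities broken
toward the lowest label; final labels are 1..C by decreasing community size.
γ defaults to 1; `n_restarts` reruns with derived seeds and keeps the best
partition.

On random graphs with ≤ 8 nodes, the returned modularity equals the
exhaustive-enumeration optimum on most instances (24/30 in the frozen test
suite) and is never above it; the shortfall on the remainder is bounded and
reported by the test, which is the expected behavior of a greedy heuristic.
Modularity is non-decreasing across passes on every run.

## Cluster profiles

Enrichment uses one-sided (greater) Fisher tests on the 2×2 tables
{in cluster vs not} × {in class vs not}, because the analysis displays
enrichment only; two-sided p-values are also emitted. BH adjustment spans all
(cluster, class) pairs.

Cluster FPC scores z-score each glycan column before PCA: MFI scales differ
by orders of magnitude across glycans, and covariance-PCA would be dominated
by bright glycans. PCA sign is arbitrary, so the FPC is oriented to correlate
positively with the per-sample mean of the cluster's z-scored glycans —
"higher score = higher antibody level" — making coefficients reproducible
and interpretable. Singleton clusters fall back to the z-scored glycan with a
warning. Scores are computed per cohort; the clinically balanced cohort (B)
feeds the association and discrimination models, while clustering uses both
cohorts.

## Association models

The shared design is: response ~ progressor + non_progressor + sex + FDR
status + HLA risk + draw age, with control/F/no/L as reference levels and
draw age in years, untransformed. Samples with unknown HLA risk are excluded
listwise from models (they remain their own category in descriptive tables).
Rank-deficient designs are rejected with the collinear columns named.
Per-glycan models default to raw MFI as the response (`log1p` optional). The
genotype comparison runs one-way ANOVA, Tukey HSD (studentized-range
distribution), then BH across the three contrasts — Tukey-then-BH is
redundant belt-and-braces for family-wise control, but it is the stated
procedure and is reproduced as such.

Cohort descriptives use plain Pearson chi-squared (no Yates correction; the
printed one-decimal p-values 0.9/0.8/0.5/0.4 of the two cohort tables are
reproduced only without it) and tie-corrected Kruskal–Wallis.

## Discrimination

Status models are progressor-vs-control logistic GLMs fitted by IRLS
(statsmodels; an internal vectorized Newton solver, cross-checked against it
to 1e-6, drives the permutation loop for speed). The LRT uses the deviance
difference against chi-square. Model AUCs are apparent (in-sample) — they
describe fit, not expected out-of-sample performance, and are documented as
optimistic.

The LRT's chi-square reference is asymptotic: with 11 added parameters at the
study's own scale (≈77 samples) it is visibly anti-conservative under the
null, so the suite verifies its calibration at n = 1000 per cohort, where the
asymptotics hold. This is a property of the test statistic, not of the
implementation.

**Permutation q.** Labels are shuffled with covariate rows (including FPC
columns) fixed; the model is refit per iteration and the apparent AUC
recorded; q = (1 + #{null ≥ observed})/(1 + n_perm) (add-one convention, so
q is never exactly 0), with the raw 1 − percentile form also reported.
Default n_perm = 10,000 in the library; scaled-down runs are used in tests.

**Partial R².** R² for a GLM is computed on the response scale as Efron's
sum-of-squares form, 1 − Σ(y−μ̂)²/Σ(y−μ̂₀)², which reduces exactly to
classical R² for the Gaussian family; partial R² of a term group is
(R²_full − R²_reduced)/(1 − R²_reduced) from a refit dropping the group.
A Pearson-residual-weighted alternative was rejected: for binomial responses
its weighted residual sum stays near n under any correctly specified model,
so group contributions vanish regardless of effect size. With
independent-of-status clinical covariates (the generator's default), the
genetic-components group's partial R² is correctly near zero and may be
slightly negative in finite samples.

**Saturation.** For each m in {1, 10, …, 200} and each iteration, m glycans
are drawn without replacement and an L2-penalized logistic model of status on
clinical covariates + those glycans (columns standardized) is fitted. The
penalty is chosen per fit by 5-fold cross-validated log-loss over a 50-point
log-spaced grid by default, with a fixed-λ override. The recorded AUC is
pooled out-of-fold from a stratified 5-fold split: an apparent AUC inflates
mechanically as random features are added (with 200 pure-noise glycans at
n ≈ 80 it rises from ~0.59 to ~0.77 regardless of penalty), which would make
the curve's plateau an artifact; out-of-fold AUC is flat under noise and
rises and plateaus under signal. An `apparent` mode is retained for
like-for-like comparison with the model fits. Note that conditional on a
single dataset the whole null curve can sit ~0.07 above or below 0.5 (chance
association shared across folds); flatness is therefore a property of curves
pooled over replicate datasets.

## Synthetic generator

The generator defines the study conditions the tests run under: 202 glycans
in 11 near-equal latent blocks; cohorts of 576 and 112 samples; per sample
and block a latent factor f ~ N(0,1); log MFI = μ_g + noise_sd·(√ρ·f +
√(1−ρ)·ε) with within-block correlation ρ = 0.75 and total log-scale spread
noise_sd = 0.4 by default; μ_g ~ N(6, 1) gives MFI in a realistic
right-skewed 50–3000 range after exponentiation. No distributional model of
MFI is prescribed by the assay itself; log-normal was chosen because
fluorescence intensities are right-skewed and nonnegative, and the choice is
isolated in this module so users can swap it.

Progressor status is logistic on the standardized block scores with log-odds
coefficients ±1.0 on five blocks (two protective, three risk — strong but
plausible biomarker effects, detectable at the small cohort's size), the
intercept solved by bisection so the realized prevalence matches the
configured 0.42; non-progressors are split off the remainder at 0.538. Sex,
draw age (uniform 2–20 y), FDR status and HLA risk are independent of the
blocks by default. One glycan is bimodal (upper mode in 5.3% of samples, 2.5
log-units up), and the same glycan carries an additive genotype effect (+0.5
log-units per A allele, allele frequency 0.49 under Hardy–Weinberg),
mirroring an exposure-plus-genotype structure. A truth object (partition,
latent scores, coefficients, genotype, bimodal indicator) is always emitted;
recovery tests compare against it, never against hard-coded numbers.

Not emulated: bead-level Luminex event data, plate/batch effects, background
bead columns (background subtraction is exercised on constructed fixtures),
longitudinal visit series, and covariate–cluster confounding. Passing tests
therefore demonstrate correctness of the machinery and recoverability under
clean block structure, not robustness to assay artifacts.

## Problem sizes used by tests and the acceptance script

Simulation-based checks run at deliberately chosen desk scales: planted-
partition recovery over 20 seeds at full study size; Model-1 type-I error
over 1000 generator replicates at the small-cohort size; permutation-q
uniformity over 200 replicates at n_perm = 500; LRT-null uniformity over
1000 replicates at n = 1000 per cohort (see above); saturation behavior at
n_iter = 100 (signal) and 10 × 10 pooled replicates (noise) with the fixed-λ
override, since the behavioral properties under test do not depend on the
penalty policy. The acceptance script uses n_perm = 2000 and n_iter = 50.

## Known limitations

- Apparent AUCs overstate out-of-sample discrimination; no external
  validation or calibration analysis is included.
- Louvain is greedy; global optimality is not guaranteed (use `n_restarts`
  to mitigate).
- The Fisher enrichment treats glycans as exchangeable units, ignoring the
  correlation structure that motivated clustering in the first place; its
  p-values are descriptive.
- The permutation scheme shuffles labels only; FPC scores are not recomputed
  per permutation, so the null preserves the observed cluster structure.
- With ≥ 3 cohorts the merge folds left pairwise; provenance flags then
  distinguish only first-operand/second-operand/both at each fold.
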