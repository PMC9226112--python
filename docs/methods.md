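# Methods

`drivenet` implements a four-stage inference chain for cancer multi-omics:
(1) identification of genetic alteration-driven genes from paired
expression/methylation/copy-number/mutation data, (2) mutual-predictability
scoring of driver × drug-response-gene (DRG) pairs on a weighted
functional-linkage network, (3) prognostic evaluation of candidate pairs as
two-gene Cox risk-score signatures, and (4) a synthetic cohort generator that
plants every structure the chain is supposed to recover, so the whole pipeline
is testable against known ground truth without any data download.

## Driver discovery

**Moderated t-test.** Differential expression between tumor and normal groups
uses an empirical-Bayes moderated t-statistic on log2 expression. For gene *g*
with pooled residual variance s²_g on d = n_t + n_n − 2 degrees of freedom, a
scaled-inverse-chi-square prior (d₀, s₀²) is estimated by matching the first
two moments of log s²_g: with e_g = log s²_g − ψ(d/2) + log(d/2), the excess of
Var(e) over ψ′(d/2) determines d₀ through trigamma inversion (solved by Brent
bracketing, which is monotone-safe), and s₀² = exp(mean(e) + ψ(d₀/2) −
log(d₀/2)). The posterior variance s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) gives
t̃_g = log2FC_g / (s̃_g·√(1/n_t + 1/n_n)) on d₀ + d df. When the observed
spread of log s² does not exceed ψ′(d/2), d₀ = ∞ and the statistic collapses
to the z-like form log2FC/(s₀·√(1/n_t + 1/n_n)); as d₀ → 0 it is the ordinary
t. Both limits are asserted numerically in the tests. A zero-variance gene
with zero effect is reported as t = 0, p = 1.

**Filters.** Differentially expressed genes (DEGs) require BH FDR < 0.05 and
fold change > 2 two-sided (|log2FC| > 1; the down direction uses FC < 1/2).
Methylation-driven genes are differentially methylated (per-gene Welch t on
beta values, FDR < 0.05) with a *negative* Pearson correlation between tumor
expression and beta at BH-adjusted p < 0.05, adjusted over the tested gene
set. The correlation uses tumor samples only (matched tumor multi-omics is
the typical case; a flag includes normals). CNA-driven genes are DEGs inside
significantly amplified or deleted regions, consumed as GISTIC-style
gene-level lists; a concordance flag restricts to amplified∩up plus
deleted∩down. Mutation-driven genes are DEGs with non-silent mutations in at
least `min_samples` distinct samples. The operation default is the permissive
`min_samples = 1`; the pipeline's study condition is `min_samples = 2`,
because with a single-sample rule any chance background mutation promotes an
already-driven gene into the mutation category, and at the 2000-gene desk
scale one such gene pollutes the mutation top-k network with its module's
pairs. Category overlap significance is the inclusive upper-tail
hypergeometric test P(X ≥ k), with the gene universe passed explicitly (the
pipeline uses the number of genes present in all modalities).

"FDR" is Benjamini–Hochberg step-up throughout, delegated to
`statsmodels.stats.multitest` behind a validating wrapper.

## Mutual predictability

A gene's direct neighbors in the functional-linkage network, ranked by edge
weight, form a retrieval list. The AUC of that list for a positive gene set is
computed in the tie-corrected Mann–Whitney (midrank) form, which is exactly
the trapezoid area under the ROC curve swept over weight cutoffs — the sweep
is kept in the package (`auc_cutoff_sweep`) as the definitional oracle and the
two are asserted equal on exhaustive tie-pattern batteries. An AUC with an
empty positive or negative class among the neighbors is *undefined* and the
pair is excluded rather than imputed at 0.5, which would flood the top-k with
noise.

A driver × DRG pair is scored by the geometric mean √(AUC_driver · AUC_drg),
where AUC_driver measures the driver's neighborhood recovering the full DRG
set and AUC_drg the DRG's neighborhood recovering the full driver set of one
category. The partner gene is not removed from its positive set (no
leave-one-out) by default; a flag enables it for sensitivity analysis. Top-k
(default 100) is taken per driver category with the deterministic tie-break
(score desc, AUC-sum desc, driver id, drg id); a pooled mode exists behind a
flag. Because the two directional AUCs factor per gene when no leave-one-out
is applied, the implementation caches them per gene, making the Cartesian
scoring O((|drivers|+|DRGs|)·d log d).

## Survival evaluation

The Cox fitter maximizes the **Breslow-ties** log partial likelihood by
Newton–Raphson with step-halving (never accepting a likelihood decrease),
tolerance 1e-8 on the max-norm of the score, at most 100 iterations; standard
errors come from the inverse observed information, Wald z gives two-sided
p-values, and HR CIs are exp(β ± 1.96·SE). Breslow was chosen over Efron as
the simplest well-defined likelihood, adequate for the generator's continuous
times; users applying the package to heavily tied real data should note that
R's `coxph` and lifelines default to Efron (the packaged cross-check test
against lifelines therefore uses tie-free data). Singular or near-singular
information (condition number > 1e12) raises an error; monotone likelihoods
are detected by an extreme coefficient (|β| > 15 on standardized inputs,
where the vanishing score would otherwise masquerade as convergence) and
flagged non-converged.

Pair evaluation follows: univariate Cox screen per gene on standardized
(z-scored) expression, keeping p < 0.1; a two-covariate Cox fit on the pair;
the risk score β₁x₁ + β₂x₂ dichotomized at its median (ties at the median go
to the low group, for determinism); two-group log-rank (O−E with
hypergeometric variance at each distinct event time, 1 df); multivariable Cox
of the risk group adjusted for age (old > 55), ER, PR, and stage (late
III/IV), binary-encoded with complete-case exclusion of unknowns and dropping
of constant covariates; BH FDR over the adjusted risk-group p-values of all
evaluated pairs, flagging FDR < 0.05. Expression is standardized before Cox so
coefficients and the median split are scale-free — adding a constant to one
gene's expression changes nothing downstream (asserted as an invariant).

Time-dependent ROC uses the cumulative-case / dynamic-control definition with
inverse-probability-of-censoring weights from the Kaplan–Meier estimate of
the censoring distribution: cases are events with T ≤ t weighted 1/G(T−),
controls survive past t weighted 1/G(t), combined by a tie-corrected weighted
Mann–Whitney on the risk scores, at horizons of 1, 3, and 5 years by default.
The Kaplan–Meier estimator processes events before censorings at tied times.

## The synthetic cohort

The generator emulates the *shape* of a TCGA-style breast-cancer study, not
its marginal distributions: no batch structure, no subtypes, no probe-level
methylation, no segment-level copy number. Defaults (the package's study
conditions): 2000 genes, 100 tumor and 40 normal samples; 20 planted drivers
per category, 18 DRGs, 100 extra DE genes, 20 CNA passenger genes.

* **Expression**: per-gene Gaussian baselines (mean 8, SD 2 across genes) with
  unit-SD noise; planted DE genes shift by ±1.5 log2 in tumors.
* **Methylation**: per-gene baseline betas with SD-0.07 noise, clipped to
  (0, 1); planted genes shift tumor beta by ±0.3, and their expression is
  generated as baseline − 7·beta + noise, so the inverse coupling and the
  differential expression follow from one mechanism.
* **Copy number**: planted genes carry ±2 calls in 75% of tumors with a
  1.0-per-call log2 dosage effect; 2% background ±1 calls; passenger genes
  sit in the amp/del region lists without a dosage effect.
* **Mutation**: background non-silent rate 2e-4 per gene per sample (a quiet
  exome at this gene count), driver rate 0.12, 15% of records silent.
* **Network**: six modules — one per driver category plus filler modules —
  each holding its drivers, three DRGs (round-robin), and eight filler genes.
  Within-module pairs link with probability 0.7 and Beta(8,2) weights;
  background pairs with probability 0.01 and Beta(2,8) weights (stochastically
  smaller; the visANT-style weight distribution is unspecified upstream, so
  the Beta family is a free modeling choice). The planted prognostic pair's
  module edge is pinned so the pair is always network-adjacent.
* **Survival**: exponential proportional hazards h(t) = h₀·exp(β₁x₁ + β₂x₂)
  on the standardized expression of the planted pair, h₀ = 1/1500 per day,
  β = (1.0, −1.0) — strong enough that each gene's *marginal* univariate Cox
  effect, attenuated by the omitted partner (Cox non-collapsibility), still
  clears the p < 0.1 screen; independent exponential censoring at rate 1/4000 (≈30%
  censored — less censoring than real TCGA follow-up, chosen so the planted
  effect is estimable at n = 100). Clinical covariates are independent
  Bernoulli draws. An exponential baseline is used because it gives a
  closed-form simulation with known true β for parameter-recovery tests; the
  fitted model is still semi-parametric.

Randomness is one master seed with named independent substreams per modality,
so regenerating or adding a modality never perturbs another's draws, and the
same seed is byte-identical.

Passing recovery tests on this generator shows the chain correctly inverts
its own generative assumptions (linear dosage effects, module-structured
networks, proportional hazards); it does not certify behavior under real-data
pathologies such as confounded batches, non-linear methylation coupling, or
non-proportional hazards.

## Design choices where the design was open

* The directional AUC uses the **whole** category set as positives, not just
  the partner gene: "how well does this gene's neighborhood identify DRGs"
  reads as a set-level criterion. Leave-one-out is available behind a flag.
* Whether candidate pairs were pre-filtered before the top-100 cut upstream is
  unknown; no pre-filter is applied beyond dropping undefined AUCs.
* The univariate screen uses expression as a continuous covariate.
* Median-tied risk scores go to the low group; top-k ties break
  deterministically — both choices exist purely for reproducibility.
* Readers reject missing cells rather than imputing; unknown clinical strings
  map to `unknown` with a logged warning and complete-case handling.

## Problem sizes

Default test and acceptance runs use the 2000-gene cohort above; unit tests
use a 400-gene version of the same structure. The Cox grid-search oracle runs
at step 1e-3 on ≤6-subject datasets; log-rank calibration uses 2000 label
permutations; parameter recovery uses 200 replicates at n = 1000. These sizes
keep the full suite to a few minutes on one CPU while leaving every assertion
at conventional 3·SE tolerances.

## Known limitations

* Breslow ties (see above); no stratified or time-varying Cox, no
  proportional-hazards diagnostics.
* No GISTIC, probe-level methylation, enrichment analysis, or drug-database
  integration; gene identifiers are opaque strings.
* The mutual-predictability score is separable (a pair's score factors into
  two per-gene AUCs), so it cannot by itself distinguish a pair sharing a
  module from a high-scoring driver crossed with a high-scoring DRG of a
  different module; planted-pair recovery therefore depends on category sets
  being clean, which is why the pipeline applies the mutation recurrence
  condition.
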