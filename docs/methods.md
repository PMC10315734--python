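# Methods

This note records the models implemented in `targetmeta`, the choices made
where the design was genuinely open, and what the synthetic-data validation
does and does not demonstrate.

## Effect-size meta-analysis

The standardized mean difference is estimated as **Hedges' g** — Cohen's d
times the small-sample correction J = 1 − 3/(4·df − 1) — rather than raw
Cohen's d, because g is unbiased at the small arm sizes common in array
series. Both per-study and pooled confidence intervals use the normal
multiplier 1.96, matching standard meta-analysis software output.

Pooling is inverse-variance. The between-study variance τ² is the
**DerSimonian–Laird** moment estimator; iterative likelihood estimators
(REML, Paule–Mandel) are deliberately out of scope. Model choice follows
the heterogeneity rule used throughout this literature: random effects iff
I² > 50% or the Cochran Q test has p < 0.05, otherwise fixed effect.
The genome-wide screen does **not** re-select per gene: every gene is
pooled under random effects, and flagged up-regulated when pooled mean and
lower 95% bound are both positive. The screen applies no multiplicity
correction — the flag rule *is* the published decision rule, and its
false-flag behaviour is characterized empirically instead (see below).
Genes estimable in fewer than two cohorts are skipped with a logged
warning rather than erroring, since gene coverage varies across platforms.

**Egger's test** is the OLS regression of g/se on 1/se with a t(k−2) test
on the intercept. Note a structural caveat surfaced during validation: if
all studies have (near-)identical sample sizes, the regressor 1/se is
(near-)constant and the intercept is unidentified. Real multi-cohort
collections have widely varying sizes, so the synthetic study used for
reporting draws cohorts across a realistic size spread (one dominant
sequencing cohort plus smaller series); the generator accepts per-cohort
size vectors for this reason.

**Clinical subgroups** compare target expression between two levels of a
clinical variable among tumor samples only (age > 60 vs ≤ 60, male vs
female, TNM III–IV vs I–II, low vs high differentiation), each cohort
contributing one Hedges' g, pooled with the same model-selection rule.

## Diagnostic meta-analysis

Per study, AUC is the Mann–Whitney statistic (ties ½) with the asymptotic
two-sided rank-sum p. The operating point maximizes **Youden's J** over all
midpoints between adjacent unique scores; ties in J break toward the
smallest cutoff, and a single unique score degenerates to the all-positive
table with J = 0. Tables containing any zero cell receive the standard
+0.5 continuity correction on **all four** cells before logit transforms.

Sensitivity and specificity are pooled separately on the logit scale with
weights 1/(1/a + 1/b) and the same fixed/random machinery as the
effect-size module, then back-transformed. The summary ROC is the
**Moses–Littenberg** linear model D = a + bS fitted by unweighted least
squares; the implied curve logit TPR = (a + (1+b)·logit FPR)/(1−b) is
integrated by trapezoid on a 10⁻³ FPR grid. var(S) = 0 fixes b = 0;
|b| ≥ 1 leaves the curve ill-defined and the result is marked unreliable
(AUC = NaN) instead of extrapolating. The bivariate random-effects model
is a known extension, not implemented here.

## Cohort handling

Same-platform studies are merged on the **intersection** of their gene ids
(a union with missing values would break the complete-arm requirement of
the SMD), with the source study as batch label. Batch correction is a
gene-wise **location-scale adjustment**: per gene and batch, center and
scale (SD floored at ε = 10⁻⁸ on the log2 scale), then map back to the
gene's pooled mean and SD. No empirical-Bayes shrinkage and no group
covariate protection are applied; under strongly unbalanced tumor/control
ratios across batches this can attenuate true group differences — a known
limitation of the stand-in. Duplicate gene ids collapse by arithmetic mean
(deterministic and symmetric). The two-sample comparison helper gates on
Shapiro–Wilk p > 0.05 in *both* groups: Welch t if normal, otherwise
Wilcoxon rank-sum; constant samples are routed to the rank test since
normality is undefined for them.

## ssGSEA and pathway selection

The per-sample enrichment score ranks genes by descending expression (ties
broken lexicographically by gene id, which makes constant samples well
defined), weights in-set positions by |rank|^α with α = 0.25 — the
canonical exponent — and sums the difference between the weighted in-set
and unweighted out-set cumulative step functions. Scores are min–max
normalized across the whole pathways × samples matrix, so differential
"logFC" values are differences of normalized means (the field's label is
kept although scores are not logged quantities; published score
differences on unnormalized scales can be numerically much larger).
Differential testing is Welch t with Benjamini–Hochberg adjustment —
deliberately simpler than moderated-statistic pipelines, which are out of
scope. Selection requires all of: mean score higher in tumor, adjusted
p < 0.05, Pearson r with the target > 0 among tumor samples, and
correlation p < 0.05.

## Immune deconvolution

Cell fractions are **non-negative least squares** coefficients of the
sample's marker-gene expression on the signature basis, renormalized to
the simplex; the NNLS residual is reported. This is a deterministic,
testable estimator of signature-proportional abundance — not a
reimplementation of ν-SVR-based tools, and no permutation p-values are
computed. Markers missing from a sample are imputed as zero with a
warning; the marker overlap must still reach the number of cell types.
Correlations with the target (and Cox fits on fractions) use tumor
samples, matching the tumor-microenvironment question.

## Survival

Samples split at the median of target expression; ties at the median go to
the low group (the deterministic reading of an "even" split). Kaplan–Meier
curves and the log-rank test come from lifelines. The univariate Cox model
is a Newton optimization of the partial likelihood written in-package with
**Efron** tie handling (Breslow available; the two coincide without ties),
standardizing the covariate internally for numerical stability and
rescaling β exactly. Wald CIs use 1.96·SE(β) on the log scale. A covariate
is a "risk factor" when HR > 1 and the median-split log-rank p < 0.05.

## Synthetic data: what it emulates and what it does not

Expression is generated **directly on the log2 scale**:

    x_gs = baseline_g + batchshift_g(cohort) + λ_g·f_s + δ_g·σ_g·z_s + ε_gs

with f_s a standard-normal latent factor shared by the target and a
co-expression block, z_s the tumor indicator, ε Gaussian with SD 1.0, and
σ_g = √(noise² + λ_g²) the within-group SD — so the planted δ_g **is** the
true SMD. Defaults mirror the motivating study scale: 15 cohorts averaging
115 tumor vs 63 control samples (per-cohort size vectors supported),
target δ = 1.0, a 50-gene up-regulated set (δ = 1.0), a 30-gene block with
loading λ = 0.7, batch-shift SD 0.5. Block genes also carry the
up-regulation effect, so the up-set, the co-expression hits and the active
pathway genuinely overlap — without this the three-way intersection would
be structurally empty. Inert gene sets are drawn from unplanted genes
only, giving a clean active-vs-inert contrast for the selection rule. The
first three cohorts share a platform id so the merge/batch path is always
exercised.

Ancillary tables: a GMT catalog whose active set is the planted union;
a signature with 5 cell types × 10 markers (own-type values U(5,10),
off-type U(0,0.5)); Dirichlet mixtures whose first cell type is tilted by
exp(0.8·z_target); exponential survival with baseline hazard 0.02/month,
log-hazard 0.7 per SD of target expression, censoring at 60 months; IHC
scores from a latent normal shifted 2 SD in cancer, discretized through
the 0–4 proportion bins and 0–3 intensity grades (the composite is the
**product**, range 0–12, the dominant convention where sources leave
product-vs-sum unstated; bins are closed on the left, exact 75% stays in
bin 3); and triplicate Ct values with a planted ΔΔCt of 2 (fold 2⁻² =
0.25), reference gene at Ct 20, noise SD 0.05.

One master seed drives everything; per-cohort and per-table substreams are
derived by fixed offsets, so equal seeds give bit-identical output.

The generator does **not** emulate probe-level microarray artifacts,
read-count noise (expression is Gaussian on the log scale, not NB),
correlated clinical covariates, non-proportional hazards, or signature
cross-contamination between cell types. Passing tests therefore
demonstrate correctness of the estimators and decision rules under their
own model assumptions, not robustness to the full messiness of public
repository data.

A note on the IHC discrimination check: with a 2 SD latent shift the
composite score's achievable AUC is bounded by Φ(√2) ≈ 0.921, and the
sampling SE of a single AUC at n = (179, 147) is ≈ 0.015, so the
"AUC > 0.9" property is asserted on the mean over replicates (≈ 0.91),
not per draw.

## Numerical choices and degenerate inputs

- Variance floor 10⁻⁸ in batch scaling; zero-variance genes never produce
  NaN.
- Zero-variance score or fraction vectors in correlation steps are flagged
  (r undefined, p = 1) and excluded from selection rather than erroring.
- Gene-wise screening is fully vectorized (arm moments → Hedges arrays →
  DL pooling), so a 2000-gene × 15-cohort screen runs in well under a
  second.
- Cox Newton iterates from β = 0 with analytic gradient/Hessian, tolerance
  10⁻¹⁰, 50-iteration cap, and errors on non-concavity or non-convergence.
- Exit codes of the CLI: 0 success, 2 configuration error, 3 stage
  failure; stage outputs and a MANIFEST of completed stages are retained
  on failure.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
coverage and calibration loops use 100–500 replicates at the sizes named
above; the genome-wide null uses 2000 genes × 15 cohorts; the end-to-end
run uses 5 cohorts × 1000 genes with δ = 1.2. These sizes were chosen as
the smallest at which the asserted properties are statistically
well-powered.
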