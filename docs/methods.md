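# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the recovery benchmarks do and do not establish.

## The differential-ranking model

Within one cohort, the counts of sample *s* over the *D* taxa observed in that
cohort are modelled as multinomial with category probabilities

  p(s) = softmax(b₀ + b·x_s),  x_s = 1[sample s is a responder]

with intercepts b₀ unpenalized and an isotropic Gaussian penalty of weight
`reg_strength` (default 1.0, i.e. a unit-variance prior) on the differential b.
Optimization is in additive-log-ratio coordinates with the last observed taxon
as reference; reported differentials are CLR-centered (they sum to zero within
a cohort). Taxa with zero total count in a cohort are *absent* (NaN), never
zero: a coefficient of an unobserved taxon is not evidence.

Because the only covariate is binary, the pooled per-group count vectors are
sufficient statistics, and the penalized objective is a convex function of the
two group logit vectors whose Hessian is block diagonal-minus-low-rank. The
solver is an exact damped Newton iteration with O(D) cost per step
(Sherman–Morrison / Woodbury), converging in ~7 iterations at any problem
size; the convergence flag requires the sup-norm of the count-normalized
gradient below `tol` (default 1e-6). In the unregularized limit the fit equals
the closed-form pooled log-ratio contrast, which the tests exploit as an
oracle. Two consequences worth knowing:

- samples are depth-weighted through pooling, so rescaling one sample's counts
  moves the estimate unless compositions within the group coincide;
- under a 58/42 responder imbalance, a taxon observed once is more often
  observed in the larger (R) group, so barely-detected taxa carry a small
  positive offset and, after CLR centering, prevalent taxa a small negative
  one. At survey-scale sparsity and low depth this offset can dominate
  prevalence–coefficient correlations of *estimated* coefficients; the
  within-cohort permutation test absorbs it exactly, because shuffled labels
  reproduce the same offset.

## Marker selection and the log ratio

The consistency rule (threshold 0.3 on |differential|, default exclusion mode
`opposite_above_threshold`) treats an opposite-direction coefficient as
disqualifying only when it exceeds the threshold itself; the strict
`any_opposite_sign` reading is available but eliminates nearly everything
under sign noise near zero. "Characteristic only of melanoma" is
operationalized as: the threshold condition never holds in a non-melanoma
cohort. The log ratio uses no pseudocount by default — a sample with a zero
marker-sum on either side is flagged invalid and excluded, with the counts of
detected numerator/denominator taxa kept for audit; a pseudocount mode exists
for sensitivity analysis.

## Mixed models and resampling

`fit_lmm` is REML via statsmodels MixedLM with normal-approximation Wald
p-values (recorded in `fit_method`; no Satterthwaite df in the host stack).
Marginal/conditional R² follow the variance-partition convention
var(fixed)/(var(fixed)+var(group)+var(residual)), the conditional version
adding the group variance to the numerator. Near the variance boundary on
small cohorts MixedLM occasionally fails; the fit then falls back to a
profiled solver (below), labelled `reml_profiled_normal_approx`.

The permutation test (shuffle the covariate within groups, refit, two-sided on
|β|, +1 convention) and the case bootstrap (groups with replacement, then
observations within each sampled group, percentile CI) each need 10⁴–10⁵
refits. They run on a dedicated profiled REML solver for the
single-random-intercept model: with V = σ²(I + λZZ′) all GLS quantities reduce
to per-group sums and the REML criterion is a one-dimensional function of
log λ, solved by bounded scalar minimization (~1 ms per fit). The solver is
cross-checked against MixedLM in the unit tests to ≤1e-4 on coefficients and
variances.

## The prevalence-association construction

Two residual sets are correlated: the differential regressed on mean relative
abundance with cohort as a *fixed* factor, and sample prevalence regressed on
mean relative abundance with cohort as a *random* intercept (conditional
residuals). The asymmetry is deliberate and reproduced as specified; its
rationale is not restated here. Default unit is the (OGU, cohort) pair
("within each dataset independently"); a per-OGU mean-coefficient mode exists
for marker-level summaries. The threshold sweep drops taxa below each absolute
prevalence cutoff (1, 2, 3, 4, 5, 10, 20, 30, 40, 50 samples) and marks points
with fewer than 10 taxa unstable. The permutation null shuffles response
labels within cohorts and *refits the differentials* per permutation (default
200 shuffles; feasible because a cohort fit is sub-millisecond).

## Diversity and enrichment

PERMANOVA partitions squared Bray–Curtis distances (pseudo-F, R²), permuting
labels only within strata; an exact mode enumerates all distinct
within-stratum arrangements for small n and is the oracle for the Monte-Carlo
path. PERMDISP embeds by principal coordinates keeping negative eigenvalues as
imaginary axes (squared centroid distances subtract the imaginary part,
clamped at zero), uses group centroids (not spatial medians), and recomputes
centroid distances per label permutation. Monte-Carlo p-values always use the
+1 convention.

Preranked enrichment uses the weighted KS running sum (hit steps ∝
|metric|^weight, default weight 1; miss steps 1/(N−|S|)); ES is the signed
extremum, the null permutes item labels, NES divides by the mean |null ES| of
matching sign, p is one-sided by sign. The default ranking metric is
sign(coef)·(−log₁₀ p): the literal "p-value times sign" would rank the most
significant items nearest zero, contradicting how the enrichment is read; that
literal metric is available as `signed_one_minus_p`. Fisher gene-family logFC
uses per-group continuity constants 0.5/n, making group swaps exactly
antisymmetric.

## The synthetic generator

The generator emulates the statistical structure of an 11-cohort,
624-sample ICI collection; defaults are the study-scale conditions:

| parameter | default | meaning |
|---|---|---|
| `samples_per_dataset` | 39,22,38,134,164,27,29,40,14,11,106 | unequal cohort sizes; first 7 melanoma (453), rest other (171) |
| `n_ogus` | 2000 | catalog size (1,000 used in the analysis drivers) |
| `target_sparsity` | 0.96 | realized zero fraction of the count table |
| `prevalence_shape` | Beta(0.3, 3.0) | heavy-tailed occupancy, rescaled to mean 1−sparsity |
| `baseline_log_sd` | 2.0 | between-taxon spread of log baseline abundance |
| `dataset_intercept_sd` | 1.0 | per-(cohort, taxon) compositional shifts |
| `noise_log_sd` | 0.5 | per-(sample, taxon) log-abundance noise |
| `effect_sd` | 1.0 | scale of planted log response effects |
| `prevalence_effect_rho` | 0.25 | target Spearman(occupancy, effect), Gaussian copula |
| `depth_log_mean/sd` | 9.0 / 1.0 | lognormal multinomial depth (~8,100 reads) |
| `frac_allochthonous` | 0.096 | low-occupancy taxa flagged oral/food |
| `allochthonous_nr_shift` | 0.5 | extra NR-direction shift of flagged taxa |
| `response_balance` | 0.582 | responder fraction |

Zeros have two sources, deliberately separated: structural (per-(sample,
taxon) Bernoulli occupancy — taxa genuinely absent) and sampling (multinomial
at finite depth). The copula couples occupancy and effect through a latent
bivariate normal with correlation 2·sin(πρ/6), so the *base* effects hit the
configured Spearman ρ; the allochthonous shift is applied afterwards and adds
about +0.02 at defaults. Marker truth labels use the cutoff 2·`effect_sd`.
Randomness flows through named substreams spawned from the single seed
(copula, baselines, intercepts, labels, depths, occupancy draws, noise, flags,
families, quality), so a fixed seed is bit-reproducible and the streams are
mutually insulated. Row sums equal the drawn depths exactly.

What the generator does **not** emulate: real sequencing depth (8k reads vs
~13M in a real survey, so detection is far noisier here), phylogenetic
correlation among taxa, compositional interactions beyond the softmax,
covariate structure (age/gender), and batch effects beyond a cohort-level
shift. Passing recovery tests therefore shows the estimators recover *this*
generative structure at desk scale, not that the biological findings of any
real survey are reproduced.

## Benchmark problem sizes and regimes

The recovery benchmarks (`ecoresp.evaluation`, used by the tests and by
`scripts/acceptance.py`) state their conditions explicitly:

- **Differential / marker recovery**: 3 cohorts × 60 samples, 200 OGUs,
  effect SD 1.0, depth e⁹, occupancy Beta(2,2) rescaled to mean 0.7
  (sparsity 0.3), baseline log-SD 1.0, noise 0.3, 10 seeds. Rank recovery is a
  check of the estimator only where each taxon's contrast is identifiable; at
  96% sparsity and 8k reads most of a 200-OGU table is detection-limited and
  no estimator could rank it (the analysis drivers show this attenuation at
  survey scale, honestly).
- **Marker scoring**: sensitivity over planted markers with |effect| ≥
  2·effect_sd; a false discovery is a selected marker whose planted effect in
  the claimed direction does not exceed the 0.3 selection threshold — the
  population analog of the claim the rule makes.
- **Log-ratio association**: planted standardized shift 1.0, 11 cohorts × 40,
  cohort intercept SD 0.3 against unit residual SD (so the pooled-SD Cohen's
  *d* measures the planted shift), 10 seeds.
- **Prevalence link**: 5 cohorts × 80, 1,000 OGUs, sparsity 0.4, ρ = 0.25,
  3 seeds; the null-rho check uses 10 signal-free replicates at the same
  scale (its mean sits near −0.03, the imbalance artifact described above).
  The permutation-p uniformity check runs 200 replicates of a small 3 × 24,
  40-OGU null at 200 shuffles each — uniformity of a permutation p is exact
  by construction at any size, so the small size only buys runtime.
- **Permutation type-I error**: 500 null replicates, 6 groups × 15, 200
  shuffles, α = 0.05.
- **Validation behavior**: planted predictor shift 2.5 SD across 6 cohorts for
  the signal case; 20 signal-free seeds for the null; AUC checked against
  brute-force concordant-pair counting on 200 random instances ≤ 30 samples.
- **Generator fidelity**: 20 seeds at default settings, 1,000 OGUs.

## Numerical choices and degenerate inputs

Relative-abundance rows must sum to 1 within 1e-9; detection means abundance
strictly above the threshold (default 0). Spearman uses average ranks and the
large-sample t approximation, and refuses constant vectors. Rank-sum tests use
the exact null for small tie-free samples (scipy's auto method). Ranking ties
break by coefficient, then lexicographically by id, so orders are total and
reproducible. Cohorts with a single response level are marked unfit rather
than failing a run; groups too small to permute contribute identity
permutations with a warning; bootstrap replicates whose refit fails are
dropped and counted. Logistic fits are unregularized maximum likelihood with a
ridge fallback of strength 1e-4 triggered only on non-convergence; the
classification threshold is fixed at 0.5 because no other threshold is
specified by the problem. ROC averaging is vertical on a fixed FPR grid of
step 0.01 (the averaging convention is recorded with the result).

## Known limitations

- The generator's depth is ~3 orders of magnitude below real surveys; absolute
  detection rates and the size of the rare-taxon estimation offset are
  correspondingly pessimistic.
- The permutation arm of the prevalence analysis defaults to 200 shuffles (a
  flag reaches 10,000); p-value resolution is 1/201 at the default.
- Fixed-effect p-values are normal approximations; for few groups they are
  mildly anti-conservative, which is why the permutation test exists alongside.
- No crossed random effects, no survival outcomes, no phylogenetic distance
  metrics; sequence-level processing is out of scope — the package starts from
  abundance tables.
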