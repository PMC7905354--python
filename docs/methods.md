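# Methods

This note documents the statistical model behind `ccdiet`, the choices
made where the design was genuinely open, and what the simulation-based
validation does and does not establish.

## The study design being modelled

The package targets phenotyping studies on panels of inbred (e.g.
recombinant inbred) mouse strains under a diet challenge: every mouse of
a strain is a genetic replicate, so between-strain variation measures
genetic influence directly. The emulated design is 22 strains × 2
experimental diets (high-protein, HP; high-fat/high-sucrose, HS) with
4–5 mice per strain per diet (one strain contributing only 2 per diet),
204 mice in total, processed in 7 weekly batches. Mice are phenotyped at
baseline on a common reference diet (AIN-76A), housed in same-strain
sibling trios, and one sibling per trio is randomized to each
experimental diet; post-diet mice live in randomized cages of three
within diet.

## Generative model of the synthetic-data module

For trait *t*, mouse *m* of strain *i* on diet *j* in batch *k*:

```
baseline:   y = mu + s_i + b_k + c_base + eps
post-diet:  y = mu + delta_j + d_j + s_i + (sd)_ij + b_k + c_base + c_rand + eps
```

with strain `s_i ~ N(0, var_strain)`, strain×diet interaction
`(sd)_ij ~ N(0, var_interaction)`, optional random diet intercepts
`d_j ~ N(0, var_diet)` on top of fixed shifts `delta_j`, batch
`b_k ~ N(0, var_batch)`, cage effects `~ N(0, var_cage)` and residual
`eps ~ N(0, var_residual)`. All effects are Gaussian, matching the
assumptions of the linear and mixed models the package fits. Strain and
batch effects persist across timepoints for a mouse; the baseline-cage
(litter) effect also persists post-diet, alongside the new
randomized-cage effect, because shared early-life environment does not
vanish at randomization — this is also why the significance models
include both cage terms.

Draw streams are keyed by `(seed, trait)`, so adding a trait to a
configuration never perturbs the draws of existing traits. Batch
assignment deals each strain's trios round-robin over batches from a
random offset: siblings share a batch, batches stay balanced, and batch
can never be aliased with strain (a fitted-model error condition, not a
condition we wish to generate).

What the generator does **not** emulate: non-Gaussian trait
distributions (real clinical chemistries are often right-skewed —
transformations are exercised on simulated lognormal data in tests
instead), missingness mechanisms other than user-injected missing
values, litter-size confounds, body-mass scaling of calorimetry
measures, and any genetic structure between strains (strain is an
exchangeable label; there is no kinship). Passing parameter-recovery
tests therefore demonstrates correctness of the estimators under the
model they assume, not robustness to real-data pathologies.

The study-shaped preset (`cc22`) fixes per-diet trio counts at
16 strains × 5, 5 × 4 and 1 × 2 (= 102 mice per diet). The published
per-strain counts are given only as ranges, so this allocation is a
choice; its baseline effective sample size is n = 9.262, and inverting
the published baseline intraclass correlation for body fat % (0.554) at
that n reproduces the published strain F (12.44) to 0.5% and the
companion g² (0.383) to three decimals, which is the consistency check
the acceptance suite runs. Cage-effect magnitudes are nowhere stated in
the source material; the preset's defaults (a few percent of the
residual variance) are arbitrary and documented as such.

## Heritability estimators

From a sequential (type-I) ANOVA with covariates entered before strain,
MSB is the strain-after-covariates mean square and MSW the residual mean
square. With the unequal-group effective sample size
`n = (N − Σ n_i²/N)/(a − 1)`:

- intraclass correlation `r_I = (MSB − MSW) / (MSB + (n−1) MSW)`
- coefficient of genetic determination
  `g² = (MSB − MSW) / (MSB + (2n−1) MSW)`

The `2n−1` denominator accounts for the doubling of additive genetic
variance under inbreeding, so `g²` is the estimator of record for
inbred panels; both are reported. Model variants: `baseline`
(strain + week), post-diet `full` (strain + diet + week), `partial`
(strain + week), and the single-diet `HP`/`HS` fits. Effective n is
recomputed per trait and variant from the rows actually modelled.
Negative estimates are reported as computed (a `negative` flag marks
them); truncation at zero would bias the parameter-recovery
experiments.

Open points resolved here as package choices: MSW is the residual of
the covariate-adjusted model (not a strain-only model); sequential sums
of squares with strain last match the default ANOVA of the R toolchain
such studies use; the diet intraclass correlation takes the diet mean
square from the full model (sequential after week) and uses the
effective per-diet count.

## Diet effect sizes and the health score

Hedges' g divides the baseline→post-diet mean difference by the
sample-size-weighted pooled SD and applies the small-sample correction
`J = 1 − 3/(4(n1+n2) − 9)`. Sign convention: positive g means the
phenotype increased post-diet. (The source formula line reads
baseline-minus-post while its interpretation sentence says the
opposite; the interpretation — the only reading consistent with the
published table narratives — wins, and `baseline_minus_post` is
available as an option.) Magnitude classes on |g|: negligible < 0.2 ≤
small < 0.5 ≤ medium < 0.8 ≤ large, boundaries assigned upward. The 95%
CI uses the standard large-sample variance
`(n1+n2)/(n1 n2) + g²/(2(n1+n2))`; the source prints no CIs, so the
method is recorded in output metadata.

The metabolic health score is `−Σ z` over six risk factors (glucose,
insulin, glucose/insulin ratio, cholesterol, TG, body fat %), Z-scored
within stratum: all mice at baseline, each diet separately post-diet.
Mice missing any component are dropped rather than scored on a partial
sum, which would not be comparable across mice.

## Mixed models and Satterthwaite tests

The significance models follow the study's specification: diet (or the
full strain×diet factorial) plus batch as fixed effects; strain,
strain×diet, randomization cage nested in diet and baseline cage nested
in strain as random intercepts (the cage terms only, for the
interaction model, where strain×diet is fixed). REML is fit directly on
the marginal covariance `V = σ²_ε I + Σ σ²_k Z_k Z_k'` with dense
linear algebra and a bounded quasi-Newton optimizer on the profiled
deviance — study-scale designs are a few hundred rows, where this is
fast and transparent, and no installed Python mixed-model routine
exposes crossed random intercepts together with the Satterthwaite
machinery the tests need. Negative variance estimates are constrained
to the boundary at zero and flagged (`singular`), not treated as fatal.

Fixed-effect F tests use Satterthwaite denominator degrees of freedom
in the multi-df form: eigendecompose the contrast covariance `L C L'`,
Satterthwaite each eigencontrast by the delta method, pool. The
covariance of the variance parameters is twice the inverse observed
information — the finite-difference Hessian of the REML deviance taken
on the relative-SD scale (`√(σ²_k/σ²_ε)`, `√σ²_ε`), where the deviance
is smooth and even at boundary estimates. The parameterization matters:
on the raw variance scale the delta method at a boundary estimate
inflates the contrast-variance uncertainty and the resulting test is
measurably conservative. On the relative-SD scale this implementation
reproduces R's `lmerTest` F, denominator df and p-values to display
precision on shared fixtures, including boundary fits.

Small-sample behaviour (measured, 1000 null simulations per design):
with sparse strain×diet cells (3 mice per cell) the diet test runs
conservative (empirical size ≈ 0.02–0.03) and the many-df interaction
test runs inflated (≈ 0.07–0.10) — and R's `lmerTest` reproduces both
sizes on identical data, so this is the method, not the
implementation. Sizes approach nominal as within-cell replication
grows; at 10 strains × 8 mice per cell both tests sit near 0.04–0.05.
The calibration experiment therefore uses that design — reduced in
strain count from the study preset but with the replication the
approximation needs — and the sparse-design behaviour is recorded here
as a known limitation relevant to real studies with 4–5 mice per cell.

The variance partition refits the post-diet data with strain, diet and
strain×diet all as random intercepts (no cage terms, matching the
published partition) and reports each REML variance divided by the
total including the residual. With two diet levels the diet component
is estimated from two effective draws; its estimate is noisy and, with
the non-negativity constraint, modestly biased toward zero — the
recovery experiment measures the diet share a few hundredths below its
true value on average, well inside the tolerance it is tested at.

## Calorimetry

Cycle labelling uses a half-open `[lights_on, lights_off)` convention
(no tie rule is stated anywhere for boundary timestamps) and flags the
first 8 h as acclimation, excluded from all means. Sampling follows the
instrument cadence (every 42 min over ~48 h → 68 records per mouse,
floor semantics for a partial trailing interval). Energy and
macronutrient intake are exact linear maps of feed mass through a
user-supplied per-diet energy table; the only shipped constant is the
documented high-protein example fraction 40.6 g protein / 90.3 g feed.
Heat production values are consumed as exported by the instrument
software, never recomputed.

The day-night comparison is a paired two-sided Wilcoxon signed-rank
test: zero differences dropped, exact null distribution for ≤ 25
untied pairs, normal approximation with continuity correction
otherwise, and a Hodges–Lehmann pseudo-median with a
signed-rank-inverted CI from Walsh averages (matching `wilcox.test(...,
conf.int = TRUE)`, against which the implementation is frozen-value
tested).

## Correlations and multiplicity

Spearman matrices use average ranks and pairwise-complete observations
(per-trait missingness differs, so listwise deletion would waste
pairs); cells with fewer than 3 complete pairs are undefined. p-values
use the t approximation for n > 10 and exact enumeration of rank
permutations at n ≤ 10. Benjamini–Hochberg adjustment is applied per
matrix over the unique off-diagonal cells; whether baseline and
post-diet families should be pooled is unstated in the source, and
per-matrix families are the implemented choice.

## Numerical conventions

- Shapiro–Wilk gate at α = 0.05 (conventional; unstated in the source),
  then Box–Cox with an automatic `1 − min(x)` positivity shift, then
  rank-based inverse-normal scores with the Blom offset 3/8 as the
  final fallback; every stage is logged per trait.
- Exchange CSVs: comma-separated, `.` decimal, `NA` for missing, UTF-8,
  17-significant-digit floats so a write/read round-trip is
  value-identical.
- REML optimization from two starting points (relative variances 0.1
  and 1.0), L-BFGS-B with non-negativity bounds; reported quantities
  come from the better optimum.
- Simulation experiment sizes (200 replicates per heritability grid
  point, 300 null studies for calibration, 100 replicates for the
  variance partition) balance Monte-Carlo error against a single-CPU
  runtime of a few minutes per experiment.

## Known limitations

- The Satterthwaite tests' documented small-sample miscalibration at
  sparse designs (above) applies to the study-scale design itself;
  interaction p-values near 0.05 from 4–5 mice per cell deserve
  caution.
- The diet intraclass correlation with two diets rests on a 1-df mean
  square and is intrinsically noisy.
- `spearman` exact p-values enumerate up to 10! permutations; the
  n = 10 case takes seconds and larger n falls back to the t
  approximation by design.
- The health score assumes risk increases with each component
  (direction handling for protective markers would require the trait
  catalog's `risk_direction` and is not applied automatically).
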