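# ccdiet

Statistical machinery for **multi-strain, two-diet mouse phenotyping
studies**: panels of inbred (e.g. Collaborative Cross) strains
phenotyped at baseline on a reference diet, randomized to a
high-protein or high-fat/high-sucrose challenge, and phenotyped again.
Because every mouse of an inbred strain is a genetic replicate, such
designs separate genetic from dietary influence on adiposity and
metabolic-health traits without any genotyping. The package is aimed at
biostatisticians and mouse-genetics groups who need these analyses as
tested, reusable code rather than ad-hoc scripts.

## What it computes

**Broad-sense heritability from strain ANOVA.** From the between- and
within-strain mean squares (MSB, MSW) of a linear model with covariates
entered before strain, and the unequal-group effective sample size
n = (N − Σnᵢ²/N)/(a−1):

    r_I = (MSB − MSW) / (MSB + (n−1)·MSW)       intraclass correlation
    g²  = (MSB − MSW) / (MSB + (2n−1)·MSW)      coefficient of genetic
                                                determination

g² corrects for the doubling of additive variance under inbreeding and
is the estimator of record for inbred panels. Five model variants are
provided (baseline; post-diet full/partial; per-diet), plus the diet
intraclass correlation from the full model's diet term.

**Diet effect sizes.** Hedges' g with the sample-size-weighted pooled
SD and small-sample correction J = 1 − 3/(4(n₁+n₂)−9), with magnitude
classes on |g| (negligible < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large).

**Composite metabolic health score.** −Σz over six risk factors
(glucose, insulin, glucose/insulin ratio, cholesterol, TG, body fat %),
Z-scored within stratum (all mice at baseline; per diet post-diet).

**Gene×diet mixed models.** REML fits with crossed/nested random
intercepts (strain, strain×diet, randomization cage in diet, baseline
cage in strain), Satterthwaite-df F tests for diet and strain×diet
fixed effects (validated against R's `lmerTest` to display precision),
and a variance partition of post-diet traits into strain, diet,
strain×diet and residual shares.

**Calorimetry post-processing.** Light/dark cycle labelling with an
8-h acclimation window, diurnal/nocturnal means, energy and
macronutrient intake arithmetic, beam-break activity aggregation, and
paired day–night Wilcoxon signed-rank tests with Hodges–Lehmann CIs.

**Trait correlations.** Spearman matrices (pairwise-complete, exact
permutation p at small n) with Benjamini–Hochberg adjustment per
matrix.

**Synthetic studies with known ground truth.** A generator that
emulates the full design — sibling trios, cage randomization, weekly
batches, configurable variance components — so every estimator is
validated by parameter recovery. The `cc22` preset mirrors the
22-strain / 204-mouse / 7-batch study layout.

## Worked example

```python
from ccdiet import (simulate_study, summarize_design, fit_strain_anova,
                    intraclass_correlation, genetic_determination)
from ccdiet.effects_scores import hedges_g_table
from ccdiet.synthetic_data import cc22_config

table, truth = simulate_study(cc22_config(seed=42))

ds = summarize_design(table, "body_fat_pct", "baseline")
print(f"strains a={ds.a}, N={ds.N}, effective n={ds.n_effective:.3f}")

anova = fit_strain_anova(table, "body_fat_pct", "baseline")
r_i = intraclass_correlation(anova.MSB, anova.MSW, ds.n_effective)
g2 = genetic_determination(anova.MSB, anova.MSW, ds.n_effective)
print(f"MSB={anova.MSB:.2f}  MSW={anova.MSW:.2f}  F={anova.F:.2f}")
print(f"r_I={r_i:.3f}  g2={g2:.3f}")

for e in hedges_g_table(table, traits=["total_weight"]):
    print(f"{e.trait} {e.diet}: g={e.g:.3f} ({e.magnitude})")
```

prints

```
strains a=22, N=204, effective n=9.262
MSB=196.15  MSW=10.60  F=18.51
r_I=0.654  g2=0.486
total_weight HP: g=1.124 (large)
total_weight HS: g=1.804 (large)
```

Reading: at this seed the generator put ~65% of baseline body-fat
variation between strains (r_I = 0.654); the inbreeding-corrected
estimate is g² = 0.486. Both experimental diets raised total weight by
more than one pooled standard deviation (g > 0.8, "large"), the HS diet
more than the HP diet — the qualitative pattern such studies report.

The full pipeline (normalization → heritability → effects/scores →
mixed models → calorimetry → correlations) runs from the shell:

```sh
ccdiet run-all --preset cc22 --seed 42 --out results/
```

and writes per-stage CSV/JSON artifacts plus a manifest with the seed
and config hash; the same config and seed reproduce every file
byte-for-byte.

## Layout

```
src/ccdiet/
  core_data.py       tidy phenotype tables, design summaries, effective n
  synthetic_data.py  study-shaped generator with ground truth
  transforms.py      Shapiro gate, Box-Cox, rank-inverse-normal, Z-scores
  heritability.py    strain ANOVA, r_I, g², diet ICC, model variants
  effects_scores.py  Hedges' g, magnitude classes, health scores
  mixed_models.py    REML + Satterthwaite tests, variance partition
  calorimetry.py     cycle labelling, intake arithmetic, Wilcoxon tests
  association.py     Spearman matrices with BH adjustment
  pipeline.py        orchestration + validation experiments
  cli.py             `ccdiet` command-line interface
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
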