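# Methods

## Null model

The analysis trait is the per-person mean of mean arterial pressure
(MAP = 2/3 DBP + 1/3 SBP) over up to three exams, computed after adding
back the expected antihypertensive-medication effect (+10 mmHg SBP,
+5 mmHg DBP at medicated exams). The order is fixed — adjust per exam,
derive MAP, then average — and per-exam missing values are simply
omitted from the person mean. Individuals without any usable exam are
excluded rather than imputed, since score tests need an observed
response.

The null linear mixed model is

    y = X beta + g + e,  g ~ N(0, sigma2_g * 2 Phi),  e ~ N(0, sigma2_e I)

with covariates sex, mean age and ever-smoked by default (the set is
configurable). `Phi` is the *theoretical* kinship matrix: computed by
the classical recursion over a parents-before-children ordering,
stored dense per family and assembled block-diagonally (exact zeros
between families). Married-in parents with no pedigree record are
materialised as unrelated founders; kinship is autosomal, so sex never
enters it. An empirical (genotype-derived) relatedness matrix is
deliberately out of scope.

### REML fitting

`2 Phi = Q diag(lam) Q'` is eigendecomposed once (and cached on the
kinship object, so replicate studies pay for it a single time).
Rotating `y` and `X` by `Q'` makes the covariance diagonal,
`V = sigma2 * D(h2)`, `D = h2 lam + (1 - h2)`, with
`h2 = sigma2_g / (sigma2_g + sigma2_e)`. The fixed effects and total
variance have closed-form profiles at fixed `h2`, leaving a smooth 1-D
restricted likelihood maximised by bounded Brent search on
`[0, 1 - 1e-6]` (xatol 1e-9), with the boundary points checked
explicitly. When `2 Phi` is (a multiple of) the identity — everyone
unrelated — the two components are confounded; the fit warns and
returns the `h2 = 0` boundary, which reproduces ordinary least
squares. A rank-deficient design raises an error naming the collinear
columns; kinship with an eigenvalue below -1e-8 is rejected as
non-PSD (smaller negatives are clipped to zero).

## Score statistics and set tests

For a variant block `G` (alternate-allele counts; missing calls
mean-imputed per variant, which preserves the scores' zero mean):

    U = G' V^{-1} (y - X beta_hat),    C = G' P G,
    P = V^{-1} - V^{-1} X (X' V^{-1} X)^{-1} X' V^{-1}.

Monomorphic variants give `U_j = 0` and a zero row/column of `C`
automatically (the projection annihilates constants). One null fit per
phenotype replicate is shared by every set test, single-step and
multistep — all of them are score tests against the same null.

* **VC (variance-component) test**: `Q = sum w_j U_j^2` with
  Beta(1, 25)-density MAF weights by default (`w = 25 (1-maf)^24`,
  strongly upweighting rare variants). The null distribution is
  `sum_i lam_i chi2_1` with `lam_i` the eigenvalues of
  `W^{1/2} C W^{1/2}`; eigenvalues below 1e-10 of the largest are
  dropped as numerical rank noise.
* **Burden test**: `S = sum w_j U_j` with flat weights by default;
  `S^2/(w'Cw)` against chi-square(1). Algebraically identical to the
  score test of the trait on the collapsed weighted genotype sum (the
  suite verifies this to ~1e-12 relative error).

Common variants are included in sets — MAF filtering exists but is off
by default. Sets whose weights or score variance vanish entirely are
reported "untestable" with p = 1 and are never significant.

### Mixture-of-chi-square tails

No installed library provides Davies' method, so the tail probability
is computed in-package three ways:

1. **Exact inversion** (Imhof's integral form of the Davies approach).
   The semi-infinite oscillatory integral is split into intervals no
   wider than one oscillation of `sin(theta(u))` (and than the
   envelope's decay scale, after normalising by the largest
   eigenvalue), each integrated by 16-point Gauss-Legendre, vectorised
   in batches of 64 intervals, until two consecutive batches
   contribute less than 1e-12. A conservative error estimate (last
   batch plus an envelope tail bound) accompanies the value. Checked
   against the chi-square(m) closed form at equal eigenvalues (agrees
   to ~1e-12) and against 200k-draw Monte Carlo on random spectra.
2. **Kuonen's saddlepoint** (Lugannani-Rice), used when the exact
   route's error estimate is no longer small relative to p — in
   practice p below ~1e-8, where its few-percent relative error is
   irrelevant to any alpha decision.
3. **Liu-Tang-Zhang moment matching**, the last-resort fallback.

The route actually used is recorded in every result
(`pvalue_method`: davies / saddlepoint / liu; burden tests report
"normal").

## Multistep procedure

Step 1 tests each pathway's variant union (pathways are treated as one
very large set; genes are never shared between pathways). Step 2 runs
only inside flagged pathways (lazy by default; a diagnostic flag
forces full computation). Alpha schedules:

| mode | single-step gene | pathway | step-2 gene |
|---|---|---|---|
| conventional | 1e-6 | 5e-4 | 0.05 / genes-in-pathway |
| liberal | 0.005 | 0.05 | 0.05 per gene |

The liberal step-2 threshold is per gene, not family-wise. No
cross-pathway correction is applied at step 2. A structural
consequence, verified empirically over hundreds of replicates: with a
common gene-level alpha, jointly significant genes are always a subset
of single-step significant genes, so multistep power and type-I error
can never exceed single-step at equal alphas — the procedure buys its
power from the *different* (more liberal) alpha a smaller number of
pathway tests justifies.

## Synthetic cohort generator

The generator emulates a multigenerational family sequencing study.
Reference study conditions (the package defaults, chosen once):

* **Pedigrees**: 24 families, 3 generations, fixed sibships of 3;
  every non-final-generation child marries an unrelated founder
  spouse. 17 members/family, n = 408.
* **Variants**: ~30 genes x 4-16 variants; 80% rare with MAF
  log-uniform on (0.002, 0.02), 20% common uniform on (0.05, 0.5).
  Founders draw counts Binomial(2, maf); descendants receive one
  allele per parent with transmission probability count/2 — exactly
  Mendelian for unlinked variants. There is no population LD between
  variants: the score covariance is computed from realized genotypes,
  and within-family co-inheritance already exercises correlated
  scores; population-LD simulation is out of scope.
* **Effects**: a fifth of genes causal; inside a causal gene each
  variant is causal with probability 1/2 (at least one forced);
  `|beta| = effect_scale * |log10 maf|` with 80% positive signs, so
  rarer variants have larger effects, echoing standard rare-variant
  simulation practice.
* **Phenotypes**: SBP and DBP share the genetic value, a polygenic
  deviate `u ~ N(0, 30 * 2 Phi)` mmHg^2, a person-level residual
  (36 mmHg^2) and a shared exam-level noise (12 mmHg^2), plus 4 mmHg^2
  of per-trait exam noise; age (generation-anchored, 5-year exam
  spacing), sex and a persistent smoking process enter with
  conventional epidemiological effect sizes. Collapsed-MAP
  heritability works out near 0.42. Medication is assigned at an exam
  iff untreated SBP >= 140 or DBP >= 90, and recorded pressures are
  reduced by 10/5 mmHg — so the standard +10/+5 adjustment inverts
  treatment exactly, making the preprocessing step meaningful and
  testable.
* **Replicates**: genotypes, pedigree and covariates are functions of
  the cohort seed only; each phenotype replicate re-draws polygenic
  and residual noise from its own seeded stream (default 200
  replicates). The null trait is the identical generator with all
  variant effects forced to zero — polygenic and covariate structure
  retained — used for type-I-error estimation.

What the generator does **not** emulate: population LD and haplotype
structure, sequencing error, informative missingness (only optional
uniform masking), assortative mating, and trait-specific
SBP/DBP correlation structure beyond their shared components. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under Mendelian family structure, not that power estimates
transfer to any particular real cohort.

## Evaluation

Power of a unit is the proportion of replicates in which it is
significant; multistep power is *joint* (both steps), with the
pathway-only proportion reported separately. Exact Clopper-Pearson
intervals accompany every proportion because 200 replicates leave wide
uncertainty. Type-I error applies the same machinery to the null
trait and reports per-unit rates plus their mean/SD. Method
comparisons report per-gene power differences, the fraction of genes
where multistep is at least as powerful, and the mean gain.

## Problem sizes used in the checks

The shipped checks use simulation sizes chosen to make each property
sharply testable: kinship against a 100,000-drop IBD oracle; null
calibration on the n = 408 cohort with 2,000 null-trait replicates
(KS at the 1% level, rejection at alpha = 0.05 inside exact 99%
bounds); 20 random quadratic-form instances against 200,000-draw Monte
Carlo (instances outside 3 SE are re-examined at 2M draws, since a
correct value is flagged by chance in ~5% of 20-instance batches);
REML recovery of (30, 20) mmHg^2 at n = 1,003 over 200 replicates;
gating over 500 replicates (zero violations); and the designed
power scenario — one pathway of 10 genes, 6 causal, modest effects
(`effect_scale = 2`), liberal alphas — over 200 replicates. The
acceptance script runs the same computations with 1,000 null
replicates and 100 REML replicates by default.

## Numerical conventions

Coordinates are 1-based inclusive (VCF convention); gene membership
comes only from the annotation, never positional overlap. Written
VCFs are GT-only with synthetic A/G alleles. All outputs carry their
generating seeds; rerunning a pipeline configuration reproduces every
numeric output bit-identically.

## Known limitations

Single quantitative trait only (no binary traits / GLMMs), one random
effect (no multiple variance components), theoretical kinship only, no
SKAT-O-style adaptive combinations, no two-stage pathway statistics
that aggregate per-gene p-values, and no FDR-based evaluation (fixed
alpha schedules only). The medication rule and exam spacing are
plausible stand-ins, flagged as such in the configuration.
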