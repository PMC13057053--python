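# Methods

This note documents the models, conventions and numerical choices behind
`germqtl`, the places where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Germination indices

A dish is a vector of daily newly-germinated counts `n_1..n_k` out of `T`
seeds (defaults: `k = 12` daily scorings, `T = 20`).  The day index `g`
is 1-based: the first scoring at 24 h is day 1.  Mean germination time is
therefore computed and reported **in days**, the only unit the daily
scoring supports, even though hour-based reporting also circulates for
this trait.  All index sums run over days with `n_i > 0`, with
`0·log₂0 ≡ 0` in the uncertainty index.

The coefficient of variation of germination time uses the **sample**
(N−1) standard deviation of the individual germination days; the unit
tests tie this, together with U, Z and MGT, to a brute-force per-seed
enumeration oracle (expanding the counts into one day per seed and
computing means, SDs, entropies and same-day pair fractions directly).

The seed vigor index uses total seedling length (shoot + root), the
classic convention; `svi_length="shoot"` switches to shoot-only.  Whether
published SVI values use total or shoot-only length is often ambiguous —
the choice is exposed rather than hidden.

Undefined statistics (no germinated seed; a single seed for CVt or Z; a
zero control mean for a tolerance index; zero root length for the
shoot–root ratio) propagate as NaN with an `UndefinedStatisticWarning` by
default; `strict=True` raises instead.  Replicate aggregation is the
arithmetic mean, and tolerance/reduction contrasts are computed **on the
replicate means**, not per replicate and then averaged.

## ANOVA and heritability

Only balanced designs are fitted — the randomized-complete-block layout
with every genotype in every replicate (and treatment) — so all sums of
squares are closed-form contrasts of cell means; the decomposition is
cross-checked in the tests against statsmodels' OLS `anova_lm`.  Missing
dishes must be imputed upstream or the trait skipped.

In the two-way model the genotype × replicate interaction is the error
(one dish per cell).  Method-of-moments components are
`σ²_GR = MS_E` and `σ²_G = (MS_G − MS_E)/r`, clamped at zero (the
standard ANOVA-method convention).  Heritability comes in two modes:

* `entry_mean` (default): `σ²_G / (σ²_G + σ²_GR/r)`, algebraically
  `1 − 1/F_G` for the balanced design.  This is the default because
  heritability columns printed next to genotype F ratios in replicated
  trials equal `1 − 1/F` (verified on several such pairs in the
  acceptance suite), i.e. they are entry-mean heritabilities even when
  the accompanying formula omits the `/r` divisor.
* `printed`: the plot-basis ratio `σ²_G / (σ²_G + σ²_GR)`, kept for
  completeness.

In the three-way model treatments are fixed: F for treatment uses the
genotype × treatment mean square as denominator; genotype and G×T are
tested against the pooled residual.  A zero error mean square yields an
explicit infinite-F flag rather than a number.  Significance codes are
`+ * ** ***` at p < 0.1/0.05/0.01/0.001.

Pearson correlations are pairwise-complete with two-sided t tests; PCA is
the eigen decomposition of the correlation matrix of centered, scaled
traits, with component signs fixed by making the largest-|loading| entry
positive.

## MGIDI

"Standardization" is implemented as the two-stage reading that makes the
all-100 ideotype well defined: (1) direction-aware 0–100 rescaling, then
(2) column standardization for the factor-score projection.  The seven
decrease-direction traits default to {MGT, U, CVt, RFW, RSL, RRL, RRNo} —
slowness/scatter of germination and the four drought reductions — and the
direction map is an explicit, overridable configuration block, because
the identity of reversed-desirability traits is an analysis choice, not a
mathematical one.

Factor retention is Kaiser's eigenvalue ≥ 1 rule (the boundary value is
retained); loadings are `eigvec·√eigval`, varimax-rotated (Kaiser
normalization, rotation-matrix convergence 1e−8, ≤ 1000 iterations);
scores use the regression method `Z·R⁻¹·Λ_rot`, and the ideotype is the
all-100 row pushed through the same standardization and weights.  The
MGIDI distance itself is invariant under the orthogonal rotation — the
tests exploit this by checking it against an independent unrotated
eigen-projection chain, while the rotation itself is checked against a
classical pairwise-rotation varimax.

Two degeneracies need explicit handling.  Exactly collinear trait pairs —
the pace index and the reciprocal-rate index rescale to the *same*
column — make the correlation matrix exactly singular and the regression
scores meaningless; `run_mgidi` therefore drops the later member of any
pair with |r| = 1 (within 1e−10) with a warning.  A residually singular
matrix falls back to a ridge-stabilized inverse (λ = 1e−8).  ω rows of a
genotype sitting exactly at the ideotype in every factor are set uniform
(1/f) with a warning.

Selection keeps the `⌈pressure·n⌉` lowest-MGIDI genotypes (default
pressure 0.15, i.e. 10 of 63–65), ties broken by stable input order with
a warning.  Selection gains are plain relative mean differences,
`SG% = 100·(mean_sel − mean_all)/mean_all`, flagged desirable when the
sign matches the trait direction; no heritability weighting is applied.

## Single-marker QTL analysis

Genotypes are ±1 (first parent positive), so the regression slope equals
the additive effect, half the homozygous-class-mean difference.  Missing
genotypes are dropped per marker (pairwise deletion); markers with fewer
than 10 usable lines or one genotype class are skipped with a flag.
`LOD = (n/2)·log₁₀(SS_tot/SS_res)` is the Gaussian maximum-likelihood
form, `PVE = 100·R²`, linked by `PVE = 100·(1 − 10^(−2·LOD/n))`; F-test
p-values derive from the same fit.  A perfect fit reports a configurable
LOD ceiling (default 50) instead of infinity.

Permutation thresholds shuffle the phenotype across lines with a seeded
generator (seed is a required, logged parameter), record the genome-wide
maximum LOD per permutation, and take the empirical (1−α) quantile with
linear (type-7) interpolation.  With complete genotype data all
permutations are evaluated in one vectorized correlation product.

Support intervals use the 1-LOD-drop rule with linear interpolation
between the last marker above and the first below the cut, truncated at
chromosome ends; published CI endpoints are report formatting whose
construction is generally unstated, so no attempt is made to reproduce
half-unit grid endpoints.  Significant markers (LOD strictly above the
threshold) whose support intervals overlap merge into one QTL reported at
the peak marker, with map neighbours as flanking markers and strength
classes very strong (PVE ≥ 20), major (10–20), minor otherwise.

Map summaries report per-chromosome marker count, length (position of the
last marker) and density (count/length).  Genome (A/B/D by chromosome
suffix) and total rollups default to the **sum of unrounded per-chromosome
densities** — the convention that reproduces published wheat map-summary
rollups — with the plain markers-per-cM ratio available as an
alternative; the two differ by an order of magnitude and must not be
mixed.

## Synthetic-data generator

The generator's defaults are the study conditions of the assay it
emulates: 63 DH lines, 3 replicate dishes of 20 seeds, 12 scoring days,
four treatments, and the published 21-chromosome map template (3,567
SNPs, 3,150.71 cM).  Markers are placed uniformly per chromosome with the
first at 0 and the last at the chromosome length.  Each DH line is one
recombinant gamete: the first allele is a fair coin and each interval
flips with its Kosambi recombination fraction, independently across
intervals (no interference beyond the map function, no segregation
distortion, no genotyping error).

Seedling traits follow
`y = μ_t + Σ_q a_q(t)·x_q + polygene_i + rep_j + ε_ijr`.  The polygenic
line effect has a trait-specific component plus a loading on one shared
"vigor" factor, giving the strong inter-trait correlations real assays
show; dish error and small replicate effects complete the model.  Default
variances put entry-mean heritabilities near 0.9 and the four planted
QTLs (shoot length 2A:85, fresh weight 3B:102, root number 1A:111,
germination day 2B:168) in the 3–22 % PVE band, with drought-arm effects
larger than control — both bands chosen to match what such experiments
report.  Germination is per-seed: each seed fails with a
treatment-specific probability (5/25/4/15 % for C/D/CN/DN) or germinates
on `round(N(line day, 1.0))` truncated to the scoring window, with
treatment delays 0/+2.0/−0.2/+1.2 days — drought slows and suppresses
germination, nano-priming is intermediate, so tolerance indices fall
below 100 and reductions are positive on average.  The generator returns
the realized entry-mean heritability and per-QTL PVE alongside the data.

What the generator does **not** emulate: real germination-count shapes
(the truncated rounded-Gaussian day model is the simplest unimodal
choice, and real count data are reported as non-normal), genotype ×
treatment interaction beyond the treatment-specific QTL effects,
correlated non-genetic dish effects across traits, and any linkage-map
estimation error (the map is taken as truth, as in the analysis it
feeds).  Passing recovery tests therefore demonstrate that the pipeline's
estimators are consistent under the assumed model, not that the model
captures every feature of real dishes.

Everything is driven by one integer seed; identical configurations
produce byte-identical output files.

## Stochastic test calibration

The seeded simulation suite uses these problem sizes, chosen to keep the
whole test run inside a couple of minutes while leaving Monte-Carlo error
well below the tolerances: permutation thresholds with 1,000 permutations
(the full scan is a single vectorized product); per-marker type-I error
pooled over 200 null scans of a sparse 200-marker map (tolerance
0.05 ± 0.01); planted-QTL recovery over 200 full-template populations;
heritability recovery over 200 two-way ANOVAs at 65 genotypes × 3
replicates (median error ≪ 0.05); ideotype-selection allele enrichment
over 50 end-to-end pipeline runs.

Two recovery bars deserve comment because the measurements sit below
them.  At n = 63 a marker explaining exactly 20 % of line-mean variance
has expected LOD (63/2)·log₁₀(1/0.8) ≈ 3.05, below a 3.3 genome-wide
threshold, so strict-threshold recovery hovers near 55 % — the
qualitative reason analyses of such populations lower the reporting
threshold to LOD 2, where the same simulations recover the locus ≥ 85 %
of the time (both rates are computed and reported by the suite and the
acceptance script).  Likewise, with 22 traits of which the planted QTLs
control four at 10–20 % PVE each, ideotype selection enriches carriers of
all favorable alleles by roughly 1.5–2× rather than 3×; a 3× enrichment
would require the planted loci to dominate the selection index, which
would contradict the 3–22 % PVE band the generator is built to respect.

## Known limitations

* Only balanced designs; no REML or unbalanced mixed models.
* Single-marker analysis only: no interval/composite mapping, no
  epistasis, and no linkage-map construction — the map is an input.
* No multiple-testing correction across traits in the ANOVA/correlation
  reports.
* The germination-time model is a deliberately simple stand-in; fitting
  germination kinetics (Hill/Weibull time-to-event curves) is out of
  scope.
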