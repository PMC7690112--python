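# Methods

## Study design being modeled

The package targets the standard multi-environment RIL mapping design: a
biparental population of ~213 recombinant inbred lines, genotyped on a
dense bin map (~2778 bins across 12 chromosomes, each bin a
recombination-free segment treated as one marker), phenotyped for
quantitative seedling traits at three treatment levels (seeding densities
LD/MD/HD) in several independent experiments with replicated, blocked
layouts.  Genotypes are coded AA = +1 ('Nipponbare'), BB = −1 ('9311');
heterozygous (AB) and missing calls are excluded from every scan.  With
this coding a positive additive effect means the Nipponbare allele raises
the trait, and a positive additive×additive effect means the two
parental-type two-locus combinations exceed the recombinant ones.

## Synthetic data generator

**Genotypes.**  Each chromosome is a first-order Markov chain over
{AA, BB} with switch probability equal to the expected two-point RIL
recombination fraction `R = 2r/(1+2r)` at meiotic fraction `r`
(Haldane–Waddington for selfed RILs), initial state Bernoulli(½).  This
matches every two-point expectation used downstream (marginal allele
frequency ½, adjacent-bin recombinant fraction R, Haldane additivity over
consecutive intervals) without simulating generations of selfing.
Residual heterozygosity is off by default (`het_rate = 0`), reflecting a
fully inbred population; a nonzero rate overwrites calls with AB at
random, mimicking the AB calls present in real bin matrices.  The
default map (`default_map()`) has 12 chromosomes × 231–232 bins = 2778
bins with uniform inter-bin meiotic `r = 0.005625` (≈ 0.57 cM), giving a
genome of ≈ 1565 cM — the scale of a dense rice RIL map.

**Phenotypes.**  One trait is generated as

    y = μ_d + Σ_q a_q(d)·x_q + Σ_p aa_p(d)·x_i·x_j + rep + block + ε

with `x ∈ {+1, −1, 0}` (0 for AB/missing), `ε ~ N(0, σ_ε²)` i.i.d. per
observation, replicate effects `N(0, σ_rep²)` drawn per (experiment,
replicate) and block effects `N(0, σ_block²)` per (experiment, density,
replicate) — independent Normal draws, the simplest structure consistent
with a split-plot randomization.  Effects and intercepts may differ by
density, which is how genotype-by-density (G×E) architecture is injected.
Defaults (`σ_ε = 1`, `σ_rep = σ_block = 0`, effects in residual-SD units)
are chosen for verifiability: the realized field variances of any
particular experiment are not public, so the generator makes no attempt
to imitate specific trait scales.  What passing tests demonstrate is
therefore correctness and calibration of the machinery under a known
generative model — not robustness to field artifacts the generator omits
(genotyping error, segregation distortion, spatial field trends,
non-Normal residuals).

A separate helper (`simulate_variance_components`) draws
`y_ijk = μ + g_i + (ge)_ij + ε_ijk` directly from variance components for
heritability checks.

All generators accept a seed; `make_study` fans one seed out through
`numpy.random.SeedSequence` so studies are reproducible end to end.

## Trait statistics

**Line means** are best linear unbiased estimates from fixed-effects
least squares (`value ~ line + replicate + block`, replicate and block
sum-coded so line coefficients are means averaged evenly over levels).
This deliberately replaces a mixed model with random replicates/blocks:
under the balanced designs generated and analyzed here the two coincide,
and the fixed-effects fit is exact and dependency-free.  The block term
is dropped automatically when aliased with replicate.

**G×E** is the line × density interaction F-test from the classical
balanced two-way ANOVA decomposition on replicate-level data (verified
against statsmodels' `anova_lm`).  Without replication the interaction is
not testable and the call errors out; a constant trait is flagged
degenerate rather than returning a spurious F.

**Heritability** uses expected mean squares of the balanced
line × experiment ANOVA pooled over experiments within one density:
`σ²_ε = MSE`, `σ²_GE = (MS_GE − MSE)/r`, `σ²_G = (MS_G − MS_GE)/(rn)`,
negatives truncated at zero (the standard ANOVA-method convention), then
`H = σ²_G / (σ²_G + σ²_GE/n + σ²_ε/(rn))`.  Truncation guarantees
H ∈ [0, 1]; H is invariant to affine rescaling of the trait.  `n` and `r`
are taken from the data, so pooling choices are explicit in what the user
passes in.

**Parent contrast** is Welch's t on replicate-level parent observations
(the unequal-variance default is the safer reading of an unspecified
"t-test").  Correlations are Pearson on line means, pairwise-complete,
starred at P ≤ 0.05 / P ≤ 0.01.

## Genetic map

Adjacent-bin RIL recombination fractions `R` (discordant homozygotes /
informative lines) are corrected to meiotic `r = R/(2(1−R))`, capped at
0.5, and converted to cM by Haldane (`d = −50·ln(1−2r)`, default, the
historical default of marker-ordering software) or Kosambi.  Marker order
is physical bin order; no ordering algorithm is run, because bins are
physically anchored.  Apparently-unlinked adjacent bins (r at the cap)
get a flagged interval capped at 50 cM.  Because the map function used to
produce any particular published map length is typically unstated, map
length is treated as descriptive, not as a reproduction target.

## Composite interval mapping

On a dense bin map there is nothing between markers to scan, so CIM
reduces to marker-cofactor regression with scan window 0: at bin `b` the
model `y ~ x_b + cofactors` is compared against the cofactor-only model
on lines complete for all terms, and
`LOD(b) = (n_used/2)·log₁₀(RSS_reduced/RSS_full)`.  A cofactor identical
(collinear) to the tested bin is dropped at that position only.
Cofactors (default k = 3, a conventional small background set) are chosen
by forward selection on RSS with ties broken toward the lower bin index.
Genome-wide thresholds are the empirical (1−α) quantile (type-7
interpolation) of max-LOD over permutations of the trait across lines;
cofactors are re-selected inside each permutation by default so the null
reflects the full procedure (a fixed-cofactor fast mode exists).

QTLs are called at local LOD maxima above threshold (plateau ties to the
lower index); the support interval is the outermost contiguous run with
LOD ≥ peak − 1.5; peaks falling inside an accepted call's interval (or
containing an accepted peak in their own) merge into one call.  The
additive effect and Var% (100·R²) come from the single-bin model at the
peak.  A call is *main-effect* iff LOD > 3.0 and Var% > 10, else
*minor*.  Hotspots are clusters of overlapping support intervals carrying
QTLs for ≥ 2 distinct traits.

When genotypes contain AB/missing calls the scan switches to a casewise
per-bin path (identical results on complete data, verified); the dense
path is fully vectorized so 1000-permutation thresholds on a few hundred
bins take seconds.

## Single-locus additive scan

Per bin: `a = (mean_AA − mean_BB)/2` and the two-class one-way ANOVA F on
line means; bins with fewer than 2 lines per homozygote class are flagged
untested.  The screen uses the fixed critical value 3.89 (P ≤ 0.05 at
df (1, 211), i.e. 213 lines) in faithful mode; `f_screen_threshold(n)`
recomputes the exact value for other population sizes.  Confirmation
permutes line means (one shuffle stream shared by all candidate bins of a
trait, making verdicts reproducible and mutually consistent) and keeps a
bin iff no more than `α·n_perm` permuted F values exceed the observed F —
with α = 0.05 and 1000 permutations, at most 50.  Verdicts are
NIP / 9311 / NA; density comparisons report PAE/NAE counts and the seven
exclusive Venn regions, which always partition the union of the three
significant sets.

Note the two permutation nulls differ by design: the additive scan
confirms *per bin* (the screen already did the multiplicity control at
the printed threshold), while CIM controls the *genome-wide* maximum.

## Two-locus epistasis scan

Only the four double-homozygote cells enter; AB at either locus drops the
line.  The statistic is the classical unweighted-cell-means interaction
test for unbalanced 2×2 layouts: interaction contrast
`I = m₁₁ − m₁₂ − m₂₁ + m₂₂` over cell means, sums of squares computed as
if balanced and scaled by the harmonic mean cell size
(`SS_int = n_h·I²/4`, df 1), `F = SS_int/MSE` with MSE pooled
within-cell, `aa = I/4`, `Var% = 100·SS_int/SS_total`.  With balanced
cells this equals the textbook two-way ANOVA interaction F exactly
(tested against statsmodels).  Pairs with any cell below `min_cell`
(default 3) are reported untested rather than silently absent; zero MSE
yields an infinite F left to the permutation stage.

Screening uses the fixed 11.13 (P ≤ 0.001 near df (1, 209));
`f_pair_threshold(n)` gives the exact-df alternative.  The same
harmonic-mean statistic is used in screening and confirmation.
Confirmation shuffles the trait once per permutation and reuses the
shuffle for every surviving pair; a pair stands iff at most one of the
10,000 permuted F values exceeds the observed one.  That rule's actual
null probability is 2/10,001 ≈ 2×10⁻⁴ per pair (the rank of the observed
F is uniform under exchangeability), which is what the calibration tests
check against.  The screen is vectorized as indicator-matrix products, so
all pairs of several hundred bins screen in seconds; `thin` subsamples
the bin universe for larger maps, where the full pair matrix would be
memory-heavy (the 2778-bin map implies ~3.9M pairs; thinning by 4–8 is
the intended operating point there).

## Pipeline and reproducibility

`run_pipeline(RunConfig)` executes input (simulate or load) →
trait statistics → map → CIM → additive scan → epistasis scan → report
tables, writing fixed-column-order TSVs and a JSON manifest (package
version, global seed, per-stage child seeds, thresholds, table row
counts).  The global seed fans out deterministically, so identical
configs produce byte-identical outputs and any stage can be replayed.  A
stage failure raises a stage-labeled error and removes partial outputs.
Defaults mirror the analysis conventions above: LOD α = 0.05 with 1000
permutations, F screens 3.89 and 11.13, 1000/10,000 confirmation
permutations.

## Numerical choices and degenerate inputs

- Regressions use QR projections; residual variances below `1e-10·n`
  are treated as collinearity (LOD 0 / cofactor dropped).
- Quantiles are type-7 (numpy default), so permutation thresholds are
  reproducible across platforms.
- Monomorphic bins, empty 2×2 cells, constant traits, missing strata and
  unknown genotype codes are flagged or rejected with located error
  messages rather than propagating NaNs.
- Physical coordinates are 1-based inclusive on disk; all internal
  indexing is 0-based.  Readers sniff tab/comma; writers always emit
  tabs.

## Problem sizes used in verification

The test-suite and acceptance-script simulations use reduced but
representative sizes chosen to keep full verification runs to minutes on
one CPU while leaving every statistical property testable: 213 lines
throughout (matching the screening thresholds' degrees of freedom);
12 × 50 = 600 bins for additive recovery (100 replicates); 200 unlinked
bins × 50 replicates for null calibration; 300 lines and 30 bins for
epistasis power (100 runs at 10,000 permutations), 200 unlinked bins for
its null level; 12 × 25 = 300 bins for CIM coverage and error control
(1000-permutation threshold, 500 fresh null scans); the full 2778 × 213
scale for genotype-IO bookkeeping and map length.  Where a bound is
binomial (type-I error ≈ α), maps use near-unlinked bins so the
independence assumption behind the bound holds.

## Known limitations

- Heritability and G×E require balanced replication (the EMS method);
  REML for unbalanced multi-environment data is out of scope.
- The CIM model is single-QTL-at-a-time with cofactors; multiple-QTL
  model selection and between-marker interval scanning are not provided.
- The generator does not model genotyping error, segregation distortion
  or pedigree structures beyond selfed biparental RILs.
- Candidate-gene annotation and figure rendering are out of scope; the
  per-bin tracks and tables are the product.
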