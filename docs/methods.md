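# Methods

This note documents the statistical procedures implemented in `refugeo`,
the choices made where the design was genuinely open, and what the
synthetic generators do and do not emulate.

## Genetic indices

All indices are computed per population from a sample of *n* individuals.

**Haplotype diversity** — *h* = *n*/(*n*−1) · (1 − Σᵢ xᵢ²), with xᵢ the
relative frequency of haplotype *i*: the unbiased probability that two
sequences drawn without replacement differ.  Haplotypes are defined by
the nucleotide sequence *and* the coded indel characters, so two
sequences identical except for a gap are distinct haplotypes.

**Nucleotide diversity** — π = mean over pairs of (differing sites /
alignment length).  Indels are first coded as binary characters (simple
indel coding: each maximal gap run with identical start and end across
sequences is one character; runs shared by all sequences are monomorphic
and dropped) and appended to the alignment as extra sites, so a gap event
counts as a single polymorphism regardless of its length.  Within the
nucleotide part, positions where either sequence carries a gap or an N
are not compared — the indel is already scored by its character.

**Gene diversity (dominant markers)** — per locus
H<sub>l</sub> = *n*/(*n*−1) · 2p<sub>l</sub>(1−p<sub>l</sub>) with
p<sub>l</sub> the band (phenotype) frequency, averaged over loci.  Band
frequencies are used directly, the convention of the classic AFLP
toolchain; no dominant-marker null-allele (Hardy–Weinberg square-root)
correction is applied by default because it is unstable at the tiny
per-population sample sizes (n ≈ 3–4) this analysis style uses.

**Rarity (DW)** — DW_j = (1/n_j) Σ_l occ_{jl}/occ_l, each band occurrence
down-weighted by the band's dataset-wide occurrence total.  The values
satisfy Σ_j n_j·DW_j = number of retained loci exactly; loci absent from
the whole dataset are dropped with a warning.

**Jost's D_est** — per-locus within-population diversity
H_S = mean_j 2p_j(1−p_j) and total diversity H_T = 2p̄(1−p̄) are averaged
over loci and combined as D = (H̄_T − H̄_S)/(1 − H̄_S) · k/(k−1).  This
is the plug-in estimator: it is exact at the endpoints (0 for identical
populations, 1 for fixed differences) but carries a positive O(1/n) bias
under panmixia because sample frequencies understate within-population
diversity relative to the pooled mean.  At the deep-sample sizes where a
differentiation estimate is meaningful the bias is negligible; it is
visible at n ≈ 4 and users comparing very small samples should read
small D_est values (≲ 0.1) as "undifferentiated".  Values are reported
unclamped (slightly negative estimates are possible).

**Mantel test** — Pearson correlation of the lower triangles, one-sided
(greater, testing *for* isolation by distance); permutations shuffle rows
and columns of the genetic matrix simultaneously, and
p = (#{r_perm ≥ r_obs}+1)/(n_perm+1).  The default genetic distance is
pairwise D_est on AFLP bands; a plastid π-based distance can be
substituted by the caller.  Geographic distances are great-circle
(haversine, R = 6371 km).

## Refugium inference

The analysis grid covers the study bounds at a fixed cell size (default
0.1°; bounds must be integral multiples of the cell).  Every cell is
correlated (Spearman) against *all* populations — cells need not contain
populations.  Rank 1 is assigned to the most negative correlation (most
source-like cell); ties take average ranks; per-index rankings are
combined by the arithmetic mean.  The direction test correlates combined
rank with latitude: ρ > 0 places the source at the southern margin.  Two
variants are provided because "latitude" can mean the cell centroid's or
the population's: the default uses all defined cell centroids; the
`population` variant pairs each population's latitude with its containing
cell's combined rank.  The p value is the asymptotic t approximation
(grids have ~10³ cells); a permutation option exists for small grids.
Undefined cells (NaN correlations) are excluded from ranking and flagged,
not imputed.

Because every statistic in this chain is rank-based, the inference is
invariant to strictly increasing transforms of any genetic index — up to
floating-point tie granularity: a nonlinear transform can merge values
that differ in their last bits and thereby create new ties.

## Cost distance

Per-cell impedance is elevation (metres); values ≤ 0 are floored at 1 m
so edge weights stay positive (zero-cost plateaus would make shortest
paths non-unique).  Moves connect 8-neighboring cell centers and cost the
mean of the two impedances times the move length: the cell size for
orthogonal moves, √2× for diagonals.  In geographic mode the E–W move
length is 111.195 km/° × cos(latitude of the cell row) (diagonals use the
mean of the two rows) and the N–S length 111.195 km/°; a flat mode uses
raster units.  The surface is the exact multi-source Dijkstra optimum
(computed with scipy's sparse-graph solver), zero on source cells, nodata
on unreachable cells.  The source line is rasterized by flagging cells
whose center lies within half a cell of the line plus all cells the line
traverses (dense sampling at a fifth of the cell size), which guarantees
a gap-free source chain.

## Occurrence models

Binomial GLMs use the logit link, fitted by IRLS (statsmodels; deviance
tolerance 1e-13, ≤ 200 iterations — tight enough that coefficients and
standard errors agree with 2×2-table closed forms to 1e-6).  D² is the
explained-deviance fraction; adjusted D² = 1 − [(n−1)/(n−p)](1−D²) with
p counting the intercept.  Tests are Wald z.  Single-predictor screens
Bonferroni-multiply p values by the family size (default 12 for the
ecology/history/apomict screen, 3 for the cytotype cross-occurrence
pairs) and flag adjusted p < 0.05.

Perfect or quasi-perfect separation is flagged (statsmodels warning, or
any |coefficient × SD(x)| > 15) and reported rather than raised, with
deviances taken at the convergence cutoff.

**Variation partitioning** fits the seven models A, B, C, AB, AC, BC,
ABC on adjusted D² and decomposes R(ABC) into three unique fractions
(a = R(ABC)−R(BC) etc.), three pairwise-joint and one three-way-joint
fraction, plus residual = 1 − R(ABC).  The additivity identity holds to
numerical precision by construction.  Fractions may be negative and are
never truncated.  Within these internal fits, columns aliased across
blocks are dropped (the partial-regression convention), so a variable
shared verbatim between two blocks lands in their joint fraction.

**Cross-occurrence caveat.**  Restricting the cytotype cross-occurrence
regressions to apomict-containing populations conditions on the union of
the three presence indicators, which induces negative dependence even
between marginally independent occurrences.  Negative pairwise
coefficients on that subset are therefore partly expected by
construction; `apomict_cross_occurrence(..., restrict=False)` analyses
all populations and has nominal type-I error under independence.

**Predictor preparation.**  Continuous covariates are scaled to zero mean
and unit sample (n−1) variance; annual precipitation (bio12) is cube-root
transformed first to symmetrize its skew; aspect enters as divergence
from north in [0°, 180°]; the land-use indicator (0 = oligohemerobic,
1 = mesohemerobic) stays binary and unscaled.  Populations with any
missing covariate are dropped listwise with a logged warning, never
imputed.

## Synthetic generators

**Serial founder simulation.**  Demes sit on the analysis grid (default
0.1° over 9.4–13.9°E, 44.7–48.1°N → 1,530 demes).  Colonization order is
breadth-first over the accumulated-cost surface of a synthetic DEM from
one edge (the wavefront), each deme founded from its cheapest already-
colonized 8-neighbor.  Deme state is integer allele-copy counts: founding
draws 2K copies hypergeometrically from the parent's 2N (so K = N with no
drift generations copies the parent exactly), regrows binomially to 2N,
then drifts for a configurable number of Wright–Fisher generations.
Plastid haplotypes drift in parallel as a single multinomial lineage of N
copies.  Defaults — K = 8, N = 50, 5 generations per step, 370 dominant
loci, 8 source haplotypes, 68 sampled populations of 4 individuals —
were chosen once to produce a clear, realistic-looking diversity decline
across the transect; no quantitative drift parameters exist to copy, so
they are deliberately qualitative.  Dominant bands are emitted per
individual as Bernoulli(1 − (1−q)²), i.e. a band is visible if either of
two genome copies carries the allele; a haploid-band mode exists for
simpler unit tests.

What the generator does *not* emulate: multiple refugia, long-distance
dispersal, introgression, selection, marker ascertainment, or scoring
error.  Passing tests therefore show that the inference recovers a
clean serial-founder signal at realistic sample sizes — not that real
data are free of the confounders listed.

**Occurrence simulation.**  Seven continuous covariates are drawn from an
exchangeable-correlation Gaussian (default correlation 0, configurable)
and mapped to plausible raw units (the pipeline z-scores them back);
land use and the three apomict presences are independent Bernoulli;
sexual presence is Bernoulli with logit = β₀ + β_eco·x + β_hist·cd +
β_apo·z on the standardized scale.  Default effect sizes mirror the
magnitudes reported for an Alpine sexual-apomictic transect (strong
negative apomict effects −3.65/−1.56/−2.49, moderate ecological effects,
zero history effect); β₀ = 3.75 offsets the negative terms so marginal
sexual prevalence is ≈ 0.55.  Because apomict presences are generated
independently of the covariates, the expected ecology×apomict joint
fraction of the variation partitioning is ≈ 0 under these defaults — the
generator makes no claim about that fraction in real data.

**Wald-coverage check.**  Interval coverage is evaluated on a correctly
specified model: data simulated with only the three apomict coefficients
active and the jointly specified three-predictor GLM fitted.  Marginal
single-predictor fits of a multi-cause generator are non-collapsible
(their estimand is not the conditional coefficient), so they are not a
coverage benchmark.  Coverage is summarized as the mean across the three
coefficients; the rarest predictor (prevalence 0.12 with |β| = 2.49 at
n = 235) individually shows the mild small-sample overcoverage
characteristic of Wald intervals in sparse 2×2 layouts.

## Problem sizes and determinism

Simulation-based checks use 100 replicates for direction recovery, 500
for interval coverage, 50 random rasters (≤ 20×20) for the shortest-path
oracle, and a few hundred replicates for the error-rate calibrations —
sizes at which Monte-Carlo error is well below the tolerances asserted.
Every stochastic operation takes an explicit seed; the pipeline derives
per-stage substreams from one master seed, and rerunning with the same
configuration is byte-identical (verified via the run manifest's output
checksums).

## Known limitations

- Pairwise D_est at n ≈ 4 per population is noisy and biased upward;
  the Mantel r² on such data is correspondingly attenuated.
- The grid-correlation method assumes a single colonization source;
  with multiple sources the combined rank surface is multimodal and the
  latitude test can be misleading.
- Cost distance is isotropic per cell (no slope-direction anisotropy)
  and uses elevation directly as impedance.
- No spatial autocorrelation correction in the GLMs; occurrence
  observations are treated as independent populations.
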