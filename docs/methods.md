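# Methods

## Data model

The pipeline's currency is a dense nuclei × chromosomes grid of
non-negative integer crossover (CO) counts — one row per meiotic nucleus
(spermatocyte, oocyte "tetrad" reconstruction, gamete or progeny), one
column per bivalent — optionally paired with a same-shaped grid of
synaptonemal-complex axis lengths in microns. Nuclei with incomplete
chromosome coverage are dropped rather than imputed: every statistic below
needs complete rows, and imputation would inject exactly the
cross-chromosome structure the pipeline measures. Sex chromosomes are not
treated specially; callers who want them excluded drop the flagged columns
(`NucleusMatrix.drop_chromosomes`).

## Covariation statistics

**Matched-group correlation.** Chromosomes are split into two groups of
equal size (one larger by one when the count is odd) and Pearson's *r* is
computed across nuclei between the two group totals. A single convenient
partition (odd vs even chromosome numbers, parsed from trailing digits of
the ids) is provided, but the headline statistic averages *r* over balanced
partitions: all of them when the chromosome count is ≤ 16 and their number
is within the cap (default 10,000), otherwise a seeded uniform sample of
distinct partitions. Both routes are exposed and the result records which
was used. Correlations on fewer than 3 nuclei or zero-variance vectors
raise instead of returning a silent 0.

**Variance decomposition.** With population (divide-by-*n*) variances,
`total = intrinsic + covariance` holds as an algebraic identity, where
intrinsic is the sum of per-chromosome variances and the covariance term
equals the sum of all off-diagonal entries of the chromosome covariance
matrix. Population variances were chosen over ddof=1 precisely so the
identity — which *defines* the covariance term — is exact to rounding
(~1e-15 relative, asserted at 1e-9 in the suite). The covariance
contribution covariance/total is the scale-free summary used for
cross-dataset comparisons.

**Variability index.** A normal is moment-fitted (sample mean, population
sd) to the observed per-nucleus totals, and a second normal to the totals
expected under chromosome independence: analytically (same mean, variance =
intrinsic) or by pooling totals from independent column-wise permutations.
Moment fitting is used because the totals are sums of ~22 counts and are
close to normal; nothing in the pipeline is sensitive to the tail shape.
The index is the integral of max(f_data − f_null, 0), split into a hypo-CO
(lower) and hyper-CO (upper) part at the density crossings, which are
solved from the quadratic equality of log-densities. When the data fit is
broader than the null the excess lies in the two tails; when narrower, it
lies between the crossings and is split at the data mean; identical fits
give 0. Degenerate zero-sd fits raise.

## In-silico correlation manipulation

To trace how covariance and the variability index depend on the underlying
correlation without changing any chromosome's marginal distribution, each
chromosome's bivalents are pooled across nuclei and sorted ascending
(stable sort; ties keep nucleus order); pseudo-nucleus *i* receives the
*i*-th smallest bivalent of every chromosome (maximal correlation). A
shuffle fraction *f* then re-permutes a uniformly chosen fraction *f* of
every column's entries among themselves, degrading the correlation smoothly
to independence at *f* = 1. Because only within-column permutations occur,
the per-chromosome multisets — hence the intrinsic variance — are invariant
along the entire sweep (asserted in the suite). An alternative granularity
(fully randomizing a fraction *f* of whole chromosome columns,
`shuffle_mode="pools"`) is provided; both reach the same endpoints, but the
entry-wise mode traces a smoother curve and is the default. When axis
lengths are present they travel with their bivalent. Sweeps default to 10
replicates with per-replicate RNG streams derived from one master seed and
report mean ± SE.

## Gamete transmission

Assuming no chromatid interference, each CO on a bivalent joins one of the
four non-sister chromatid pairings uniformly, so a single chromatid carries
each CO with probability ½ independently: Binomial(k, ½) per chromosome.
Mode 1 (default) samples one gamete per meiocyte, avoiding sibling
correlations; mode 4 samples all four chromatids with the complementary
constraint (the four counts sum to 2k exactly) for tetrad-style analyses.
The closed forms

    total_g = intrinsic_m/4 + X/4 + covariance_m/4
    contribution_m/contribution_g = 1 + X/total_m = 1 + 1/(X·CV²)

follow from the law of total variance (the X/4 term is the binomial
sampling variance E[T/4]) and are verified against simulation in the suite.

**Type-II augmentation.** Interference-free COs (~10% of totals in humans)
are added per chromosome as independent Poisson counts with mean
fraction × (that chromosome's mean), so higher-mean (longer) chromosomes
receive proportionally more random COs and the expected total rises by the
fraction. Being independent of everything, they dilute the matched-group
correlation.

**Maturation.** CO maturation inefficiency (M < 1) is modelled as
independent binomial thinning per bivalent — each designated CO matures
with probability M, with no spatial structure. Thinning scales the mean by
M and, by adding binomial noise, lowers the matched-group correlation.

## Chromosome-pair analyses

Pairs are formed either between adjacent chromosomes after sorting by mean
metric (CO count or axis length; ties broken by id for determinism) or over
all C(n,2) pairs. Each pair's Pearson *r* across nuclei carries a
percentile-bootstrap 95% CI (default 2,000 resamples of nuclei with
replacement; degenerate zero-variance resamples are redrawn) and
SE = ΔCI/3.92, the normal-theory width-to-SE conversion. The trend of *r*
against the pair's mean metric is summarised by an ordinary least-squares
line — the minimal model for an approximately linear scatter, exposed so a
different family can be substituted — plus the scatter's own Pearson
correlation. A sweep-based correspondence curve maps mean adjacent-pair
correlations onto the matched-group scale by running the in-silico sweep
and recording both statistics at every achieved correlation level; the
curve is constructed empirically rather than analytically because the
mapping depends on the marginals of the data at hand.

## Beam-film simulator

The simulator implements the classical parameter roles with one admissible
set of functional forms, each isolated behind a small function so
alternates can be swapped:

| parameter | meaning | default | form |
|---|---|---|---|
| N | mean precursors/bivalent | 13 | count ~ Binomial(round(N/B), B) |
| B | precursor-number regularity ∈ (0,1] | 0.8 | B = 1 ⇒ exactly N |
| E | placement regularity ∈ [0,1] | 0.6 | E·(even anchors) + (1−E)·(sorted uniforms) |
| Smax | max designation force | 3.5 | threshold fixed at 1 |
| A | sensitivity shape | 1.0 | sensitivity ~ Uniform^(1/A) |
| L | interference distance (µm axis) | 10 | factor 1 − exp(−d/L), two-ended |
| M | maturation efficiency ∈ (0,1] | 1.0 | independent thinning |
| axis_length | bivalent axis (µm) | 15 | continuous positions |

Designation is greedy: while any precursor's sensitivity × locally
available force (Smax times the running product of interference factors
from prior designations) exceeds 1, the largest is designated. The male-like
default (N = 13, axis 15 µm, L = 10 µm) yields ~1.9 mature COs per
bivalent, < 1% zero-CO bivalents (the obligatory CO), coefficient of
coincidence ≪ 1 at distances below L recovering to 1 far beyond it, and a
strongly sub-proportional (~1.05×) CO response to precursor doubling (CO
homeostasis). Axis-length variation is emulated by mixing two
subpopulations that share L (in microns) but differ in axis length with
proportionally scaled precursor numbers; all chromosomes of a nucleus come
from one subpopulation, and re-assorting a fraction of each chromosome
column across nuclei tunes the axis-length correlation between its maximum
(a two-point mixture with perfectly coupled group totals) and 0.

## Synthetic-data generator

A per-nucleus latent factor g ~ Gamma (unit mean, variance σ_g²) — the
statistical stand-in for nucleus-wide axis-length scaling — multiplies
every chromosome's Poisson rate; counts are optionally zero-truncated
(obligatory-CO floor, implemented by redrawing zeros) and binomially
thinned by M. Axis lengths, when coupled, are base length × g × small
lognormal noise (sd 0.08). The knob rho ∈ [0,1) targets the *expected
matched-group correlation of the observed counts*: under the pure Poisson
mixture σ_g² = 2ρ/((1−ρ)X) in closed form, but truncation and thinning
attenuate the correlation, so σ_g² is solved numerically through the full
observation model (zero-truncated, thinned moments integrated over a
quantile grid of the latent factor). Likewise each chromosome's underlying
rate is solved so its *observed* mean hits the configured target despite
the floor. The shipped calibration table
(`src/meiocovar/data/calibration_rho.csv`) records the empirically achieved
correlations on a rho grid for both presets; achieved values agree with rho
to ~0.005.

Preset defaults reflect published human pachytene values: male-like —
755 nuclei, 22 bivalents, ~50 MLH1 foci per nucleus with a descending
per-chromosome gradient (≈3.5 down to ≈1.05), mean axis 15 µm, rho = 0.65,
M = 1; female-like — 69 nuclei, observed totals 1.5-fold the male values,
axes 2-fold, rho = 0.78, and maturation efficiency M = 0.6 (the magnitude
reported for human female CO maturation inefficiency), with designation-
stage means inflated by 1/M so observed totals still hit their target.

**What the generator does and does not emulate.** It reproduces the
per-nucleus covariation structure, obligatory CO, sex differences in count
level and maturation, and count–axis coupling. Its marginals are
(truncated) mixed-Poisson, i.e. *more dispersed* than real MLH1 counts,
which interference regularizes to sub-Poisson variance. Consequently
absolute variance levels — and downstream quantities that depend on the
intrinsic/X balance, such as the gamete-level matched-group correlation
(~0.42 male-like here) — run higher than values measured on real sperm
data. Passing tests therefore demonstrate the correctness of the statistics
and the qualitative orderings, not the absolute values of any particular
human dataset; the real-data checks in the suite require the published
per-nucleus tables placed under `data/human/`.

## Problem sizes and numerical choices

The suite and the acceptance script use sizes chosen to keep Monte-Carlo
error well below the asserted tolerances while remaining quick on one CPU:
2,000–5,000 nuclei for correlation/variance recovery, 755/69 nuclei (the
study sizes) for the preset populations, 10–20 gamete replicates for the
closed-form checks, 200 runs × 1,000 resamples for bootstrap calibration,
3,000–4,000 bivalents for beam-film rates, and 60–500 sampled balanced
partitions (out of C(22,11)/2 ≈ 3.5 × 10⁵) for grouped correlations —
partition-sampling SEs are ~0.003, negligible against the effects measured.
Density-crossing solutions fall back to a midpoint split for equal-sd
normals; brentq tolerances are 1e-8 to 1e-10. All stochastic code takes
either an integer seed or a numpy Generator; orchestrated runs derive
per-stage streams from one master seed and record it in the manifest.

## Known limitations

* Variability-index normal fits are moment-based; for very small nuclei
  counts (< 30, warned) or strongly skewed totals the excess-fraction
  estimate is noisy.
* The beam-film functional forms are one admissible instantiation of the
  stated parameter roles; only ordering/qualitative behaviour is asserted,
  and no best-fit parameter estimation to real datasets is provided.
* The trend over pair size is summarised linearly; curvature in real data
  is not modelled.
* The generator's latent factor is a single global scaler: it cannot
  produce chromosome-specific covariation gradients (long pairs more
  correlated than short ones) — use the beam-film mixed-population route
  for that structure.
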