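# Methods

This note records the statistical model behind `benthograd`, the default
parameter values and why they were chosen, and the places where the design
was genuinely open.

## Disturbance classification

The mosaic extent is rasterised at `cell_size` = 0.5 m.  A cell belongs to
the grid iff its centre lies strictly inside the extent polygon (centre
rule), so partial edge cells smaller than half a cell are dropped and
Σ level areas equals the centre-rule extent area exactly.

Distance is measured from each cell centre to the nearest *track stripe* —
the centreline buffered by half the track width with flat caps — not to the
centreline itself.  Cell centres inside a stripe have distance 0.  Measuring
from the stripe edge makes the innermost band "the tracks plus a 1 m rim",
which is what a visual track classification delineates; in-track cells must
carry the highest disturbance level.

Bands are half-open intervals on distance d:
A: d ∈ [0, 1), B: [1, 10), C: [10, 50).  Half-open intervals make the bands
a partition; with 0.5 m cells and metre-valued band bounds, cell-centre
distances avoid the boundaries anyway, so the tie rule is measure-zero in
practice.  Cells with d ≥ 50 m in a tracked scene are UNCLASSIFIED and take
no part in sampling.  A scene without tracks carries the +infinity distance
sentinel and classifies entirely as the reference level D.

## Composite sampling units

Within each level, `cells_per_unit` = 14,000 cells (3500 m² at 0.5 m) are
drawn uniformly at random *without replacement* per replicate unit;
defaults are 5 replicates for A, B, C and 10 for D.  Units are scattered
cell sets, not contiguous quadrats — this is deliberate: the randomisation
destroys the spatial coherence of the data, and with it small-scale spatial
autocorrelation between neighbouring cells, so units can be treated as
independent replicates.  No minimum-separation constraint is imposed on the
drawn cells.  Each level draws from an independent substream
(`SeedSequence(seed, spawn_key=(level,))`), so adding or removing a level
never perturbs another level's draw.  Specimens map to cells by half-open
intervals [lo, hi) in both axes; specimens in unsampled cells or outside the
raster are dropped and counted.

## Community metrics

Densities are individuals per hectare over the unit's exact cell area.
Diversity uses Hill numbers of order 0, 1, 2 on the morphospecies columns
only (higher-taxon groups serve only to aggregate densities; records
identified only to a higher taxon would inflate richness):

- S — number of morphospecies with non-zero count;
- exp[H′] with H′ = −Σ pᵢ ln pᵢ (natural log; the exponential form makes the
  base immaterial);
- 1/D with D = Σ pᵢ².

S ≥ exp[H′] ≥ 1/D always, with equality only under perfect evenness; an
all-zero unit returns flagged missing values, never 0.  Rarefaction uses the
exact hypergeometric expectation evaluated with log-gamma (no resampling;
Monte-Carlo subsampling survives only as a test oracle).

## Univariate comparisons

Each metric is fitted against disturbance level as a saturated one-factor
GLM (one-hot design, no intercept, IRLS), so fitted level means equal
observed level means.  Count metrics use quasi-Poisson errors: Poisson
log-link point estimates with dispersion φ̂ = Pearson χ²/df_resid inflating
all covariances (the conventional quasi-likelihood estimator; deviance-based
φ is not offered).  Diversity metrics use Gaussian errors, where φ̂ is the
residual mean square.  The global test is a quasi-F on scaled deviance
differences, F = (D₀ − D₁)/(df₁·φ̂) against F(df₁, df₂); in the Gaussian
case this is exactly the classical one-way ANOVA F (asserted against an
independent sum-of-squares oracle in the tests).  Likelihood-ratio and Rao
variants are not offered.

All k(k−1)/2 pairwise level contrasts are tested simultaneously.  Contrast
t-statistics use model-based standard errors (already scaled by φ̂) with
df = df_resid.  The single-step adjustment is
p_adj = P(max_i |T_i| ≥ |t_obs|) under a multivariate t with the contrast
correlation matrix, evaluated by scrambled-Sobol quasi-Monte-Carlo
integration (8 scrambles × 2¹⁶ points, fixed seed; the scramble-to-scramble
standard error is reported, ≲ 3·10⁻⁴ for mid-range p and well below 10⁻⁴
near the 0.05 decision region).  The contrast correlation matrix of a
one-factor design is always singular (rank k−1); sampling uses its
eigendecomposition, which handles this exactly.  With two levels the single
contrast short-circuits to the exact univariate t.  A level whose counts are
all zero puts the log-link mean on the boundary: the fit falls back to the
saturated closed form (flagged `boundary`), and pairwise contrasts involving
that level are reported as flagged missing values rather than numbers —
their Wald statistics are not defined.

Effect size is η² = SS_between/SS_total on the response scale.  Compact
letter displays use insert-and-absorb: two levels share a letter iff their
adjusted p ≥ α; intransitive patterns give a level several letters.

φ̂ = 0 (degenerate constant data) is reported as F = 0, p = 1 when the
between-level deviance is also zero, and as a flagged infinite F with p = 0
otherwise.

## Multivariate comparisons

Bray-Curtis dissimilarity is computed on square-root transformed unit ×
morphospecies counts.  ANOSIM ranks all n(n−1)/2 off-diagonal
dissimilarities with midranks for ties and forms

    R = (r̄_between − r̄_within) / (M/2),  M = n(n−1)/2,

which equals 1 when every between-group dissimilarity exceeds every
within-group one.  When the number of distinct label arrangements is at most
`max_exact` = 200,000 the permutation distribution is enumerated completely
and p is the plain fraction of arrangements with R ≥ R_obs (the observed
arrangement is part of the enumeration, so the minimum p is 1/total — e.g.
1/3003 for 5 vs 10 replicates, 2/252 for 5 vs 5 where the complementary
arrangement ties).  Larger problems use 9,999 seeded random permutations
with the observed arrangement added to numerator and denominator
(guaranteeing p > 0); the scheme, denominator and seed are reported.
Pairwise follow-ups extract each pair's submatrix and re-rank it before
computing R, and carry no multiplicity adjustment.

The ordination is non-metric MDS (SMACOF with isotonic disparities) in k = 2
dimensions from 20 random starts (500 iterations, tolerance 1e-7); the best
configuration is centred, rotated to principal axes with a deterministic
sign convention, and reported with its Kruskal stress-1 recomputed by the
package's own isotonic-regression helper, independent of the optimiser's
internal criterion.

## Kernel-density heat maps

Per-group surfaces use a quartic (biweight) kernel,
K(r) = 3/(πh²)(1 − r²/h²)² for r < h, with bandwidth h = 20 m on a 1 m
grid — the kernel commonly documented for GIS kernel-density tools.  The
kernel integrates to 1 over its support disc, so the surface integrates to
the group's specimen count over an unbounded domain; no boundary correction
is applied, so specimens within 20 m of the extent edge lose mass, matching
typical GIS behaviour.  Class breaks are 10 equal-width intervals from the
surface minimum to maximum, scaled per group (not globally); a constant
surface yields a single degenerate class, flagged.

## Synthetic scenes and communities

The generator emulates two photo-mosaic footprints: a disturbed extent
("DEA", default 5.86 ha as 586 m × 100 m, with plough tracks) and an
untracked reference extent ("REF", default 5.25 ha).  Tracks are parallel
8 m-wide stripes spanning the extent; the spacing argument accepts a cyclic
gap pattern so clustered layouts can be expressed.  The default DEA layout
is 20 tracks in 10 paired clusters (10 m between paired centrelines, 47 m
between pairs).  This choice is forced by sampling feasibility: each of
levels A, B and C must supply 5 × 14,000 cells = 1.75 ha, and evenly spaced
tracks cannot produce that much of all three bands inside 5.86 ha (the B
ring is always 1.8× the A stripe, which starves C).  The paired-cluster
layout yields exactly A = 2.00, B = 1.80, C = 2.06 ha under the centre-rule
raster — every band feasible with margin at the real survey's extent.  Real
plough tracks are likewise unevenly spaced and frequently overlapping.

Megafauna are generated as an inhomogeneous Poisson point process: for each
classified cell the count is Poisson with mean intensity(level) × cell area,
and positions are uniform within the cell — complete spatial randomness
within each level, the simplest model consistent with density-by-level
summaries.  A Thomas-cluster switch (`cluster_mean` offspring per parent,
Gaussian spread `cluster_sd`; off by default) exists to probe robustness to
within-level clustering; no parameter values for it are claimed from any
survey, and offspring that disperse outside their level's cells are
discarded, so realised intensity dips slightly below nominal for narrow
bands when it is on.

Default per-level intensities are 649/790/798/592 ind ha⁻¹ for A/B/C/D, with
group mixtures that put the ophiuroid share at 23% in the reference level
and 32–35% in the disturbed levels — the dominance shift the analysis is
designed to detect.  Each individual draws a higher-taxon group from the
level mixture and then a morphospecies from a geometric rank-abundance
series nested within its group (97 morphospecies over 7 groups; the same
series at every level, so between-level dominance differences arise from the
group mixtures alone).  The geometric decay default of 0.35 was calibrated
once against the per-unit diversity ranges the default intensities imply
(mean S ≈ 41–49 and exp[H′] ≈ 24–31 per 3500 m² unit, with heterogeneity
diversity lower in the disturbed levels) and then frozen.  Body sizes are
drawn from a lognormal (ln-mean ln 9 cm, ln-sd 0.55) truncated at 5 cm;
sizes play no analytical role beyond the > 5 cm inclusion filter.
Positions and sizes are quantised to 10⁻⁶ so specimen tables round-trip
losslessly through the text format.

What the generator does *not* emulate: within-level spatial structure tied
to nodule patches or microtopography, inter-specimen interactions
(attraction/avoidance), detection error and misidentification in image
annotation, navigation/position error, and morphospecies turnover between
extents (the species pool is shared).  Passing tests therefore demonstrate
that the pipeline recovers known parameters and calibrates correctly under
its own model assumptions — not that those assumptions hold for any real
seafloor.

## Numerical choices and degenerate inputs

- Coordinates are metres from the scene origin, x east, y north; all rasters
  share this frame.  Per-stage seeds derive from
  sha256(master_seed, stage name) mod 2³¹−1.
- GLM convergence: IRLS to relative tolerance 1e-10 (statsmodels backend);
  the saturated closed form is used on boundary or zero-variance data.
- Wald confidence intervals for level means are formed on the link scale
  with t(df_resid) quantiles and back-transformed, giving asymmetric
  intervals for count metrics.
- Rarefaction with n > N raises; n = 0 returns 0; all-zero count vectors in
  Hill numbers or dominance shares return flagged missing values.
- Bray-Curtis on an all-zero row raises, naming the row.
- ANOSIM requires every group to have ≥ 2 members (within-group ranks are
  undefined for singletons).
- Dissimilarity rank ties take midranks; this affects R only in degenerate
  (heavily tied) data.

## Problem sizes

The default desk-scale configuration (5.86 + 5.25 ha, 0.5 m cells, ≈ 7,300
specimens, 25 composite units) runs end to end in well under a minute on a
single CPU.  The repeated-simulation checks in the test suite use 500
pipeline replicates for parameter recovery and 2,000 replicates for type-I
error calibration of the quasi-F under negative-binomial nulls — sizes
chosen so binomial error on the estimated coverage/rejection rates is a few
tenths of a percent.

## Known limitations

- The pairwise-contrast adjustment assumes the multivariate t with
  df = df_resid; software that adjusts GLM contrasts against a multivariate
  normal will give slightly smaller adjusted p-values.
- Boundary (all-zero) levels yield flagged missing pairwise p-values rather
  than a resolved significance decision; letter displays treat those pairs
  as not-significant.
- No coverage-based (Chao-type) richness estimation, PERMANOVA, SIMPER or
  dispersion tests; mixed models and explicit spatial-autocorrelation
  corrections are out of scope (the randomised composite-unit design is the
  intended answer to autocorrelation).
- Heat-map surfaces lose kernel mass at extent edges by design.
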