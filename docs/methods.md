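# Methods

## The analysis chain

The pipeline quantifies the shape of a nearly flat, bilaterally
symmetric bone from its 2-D outline and dissects the genetic control of
that shape in a mouse intercross / congenic design.  The chain is:

1. **Outline acquisition model.**  Each specimen is a closed outline of
   ~100 points, evenly distributed along the curve, plus four homologous
   control points: the rostral and caudal midline points and the two
   maximal-width lateral points.  Outlines travel in TPS text files
   (`morphoqtl.tps`); coordinates are taken as already scale-calibrated,
   y-axis up, and no pixel conversion is applied.

2. **Superimposition** (`morphoqtl.geometry`).  A generalized Procrustes
   analysis is run on the four control points only: configurations are
   centered, scaled to unit *centroid size* (the root summed squared
   landmark-to-centroid distance), and rotated by proper rotations to
   minimize the summed squared distance to the consensus, iterating
   until the consensus moves less than 1e-10 (4-landmark fits converge
   in a handful of iterations; 100 is the hard cap).  The fitted
   rotation of each specimen is then applied to its outline, which is
   first centered on its *own* centroid and scaled by the square root of
   its *own* area.  The two size measures are deliberately distinct:
   centroid size normalizes the landmark fit, √area normalizes the
   outline, and they are never conflated.  Re-centering uses the outline
   centroid (not the control-point centroid); this is one of the places
   where the procedure was genuinely open and the choice is recorded
   here.

3. **Elliptic Fourier description** (`morphoqtl.efa`).  Outlines are
   expanded in the Kuhl–Giardina basis using a piecewise-linear
   arc-length parameterization.  With H = 30 harmonics the analysis
   vector has exactly 4H = 120 coefficients; the DC terms (A0, C0)
   encode location only and are excluded.  No "first-ellipse"
   normalization of rotation, scale or starting point is applied —
   Procrustes superimposition on the control points plus the
   rostral-midline start anchor already standardize those degrees of
   freedom, which keeps the coefficients comparable across specimens
   without discarding the first harmonic's shape information.

4. **Symmetrization.**  The biologically meaningful signal is the
   symmetric component of the outline.  The outline is reflected about
   the axis through the two midline control points, re-ordered to stay
   counter-clockwise with the homologous start point, rotationally
   aligned to the original, and the two copies are averaged.  The
   average is rotated by half the aligning angle, which makes the result
   *exactly* mirror-symmetric about the axis: symmetrization is an exact
   projection (idempotent, and the identity on already-symmetric
   outlines, both to machine precision).  For equally spaced outlines
   (the pipeline always resamples first) averaging point sequences and
   averaging Fourier coefficients are the same linear operation.
   Symmetrization runs after alignment and normalization.

5. **Dimension reduction and scoring** (`morphoqtl.stats`).  The 120
   coefficients go through a centered PCA; 15 components are retained by
   convention (an 8-fold reduction; on the synthetic data 15 components
   carry ≥99% of the variance, see `analysis/02_outline_conditions.py`).
   Group discrimination uses classical canonical variates: generalized
   eigenvectors of between- versus pooled within-group covariance,
   scaled to unit pooled within-group variance, min(g−1, K) axes.  Axis
   signs are fixed so the recipient-strain (B6-like) reference group
   takes the higher mean — this matches the convention that recipient
   homozygotes score above donor homozygotes.  The single canonical axis
   of the two-parental-strain analysis, applied to F2 individuals'
   PC scores, is the quantitative phenotype for mapping.  Classification
   is nearest group mean in canonical space with equal priors (designed,
   balanced groups); exact ties break toward the group earlier in label
   sort order.  Leave-one-out cross-validation refits the discriminant n
   times.

6. **Group inference.**  Pairs of groups are compared with Hotelling's
   T² (T² = n₁n₂/(n₁+n₂)·D², D² the pooled-covariance Mahalanobis
   distance), converted to F on (p, n₁+n₂−p−1) degrees of freedom with
   p the dimensionality used.  A historical variant that replaces p by
   the number of groups in the analysis batch is available as
   `df_convention="groups"`; it is not the default because it is
   inconsistent with the T² sampling distribution.  p-values are
   Bonferroni-corrected over the pairwise comparisons of each analysis
   batch.  Power is the observed-effect plug-in: noncentral F with
   noncentrality λ = T²; it is computed for every test and flagged for
   reporting when raw p falls in 0.05–0.1, the band in which it is
   conventionally quoted.

7. **QTL mapping** (`morphoqtl.qtl`).  Genotypes are observed at the
   markers, so the scan is marker regression on the 3-class genotype
   model — no hidden-Markov interval mapping; the donor segments are
   short and congenic confirmation, not interval estimation, is the
   inferential core.  LOD = (n/2)·log10(RSS₀/RSS₁).  Genome-wide 5%
   significance comes from phenotype permutations (default 1000,
   seeded): the 95th percentile of the per-permutation maximum LOD.
   Missing genotypes are dropped per marker (complete-case), never
   imputed.  Epistasis between marker pairs uses two-way fixed-effects
   ANOVA with type-II sums of squares (robust to unbalanced cells).
   The allele-dose profile sums donor alleles over two markers (0–4)
   and reports per-dose means with a linear-trend test.

## The synthetic cohort

No raw outlines are publicly deposited, so the pipeline ships a
generator (`morphoqtl.simulate`) that emulates the *structure* of the
study's data and makes every downstream stage testable.

**Outline model.**  A smooth closed curve built from a superellipse of
length L and caudal width Wc (corner exponent 2/corner_round), whose
half-width tapers linearly to the rostral width (ratio r), with a
Gaussian notch indenting the caudal midline (depth dn·L) and a Gaussian
lateral depression near the rostral end (amplitude dl).  The upper half
is computed and mirrored, so the noise-free curve is bilaterally
symmetric to the last bit; points are resampled to equal arc length
starting at the rostral midline vertex.  Per-point radial noise models
digitizing error and breaks symmetry; independent control-point jitter
models landmark placement error (the two are separately tunable on
purpose).  A random rigid rotation (±0.15 rad), translation (±0.5) and
global scale (0.9–1.1) are nuisance transforms the alignment must
remove.  Parameter combinations whose curve self-intersects (deep notch
plus very sharp corners) are rejected with a diagnostic.

**Shape poles.**  The recipient ("B6-like") pole is rectangular
(r = 1), notched (dn = 0.16), laterally depressed (dl = 0.10), with
moderately sharp corners; the donor-carrier ("66H-like") pole is
trapezoidal (r = 0.78), more deeply notched (dn = 0.26, matching the
carrier strain's deeper notch), undepressed and rounder.  Units are
arbitrary; only relative geometry matters after normalization.

**Genetic architecture.**  Three donor segments with the study's
printed boundary-marker positions: Chr1 87.599477–119.094898 Mb
(31.5 Mb), Chr13 93.838592–103.968912 Mb (10.1 Mb), Chr18
42.783975–56.096090 Mb (13.3 Mb).  Markers on one chromosome recombine
with Haldane probability at 1 cM/Mb (a standard mouse approximation;
only relative linkage matters); different chromosomes segregate
independently.  Phenotype model per individual: shape parameters =
recipient base + Σ_l dose(g_l)·effect_l, with dose 0 / (1+dominance)/2 /
1 for B/B / B/S / S/S, and each locus's effect scaled by
(1 − suppression) for every epistasis term whose modifier locus is
donor-homozygous.  The Chr1-like and Chr18-like loci carry 55% and 45%
of the pole-to-pole difference; the Chr13-like locus has no own effect.

**Noise and effect-size calibration.**  The study does not quantify
effects in shape-parameter units, so the preset was calibrated once to
the design properties the analyses assume: residual per-individual shape
noise is Gaussian along the total-effect axis with s.d. 0.18 of the
pole-to-pole difference plus a small independent per-parameter floor,
giving each causal locus a homozygote gap of roughly 2.0–2.4
within-class s.d. on the discriminant score — large enough that a
91-individual F2 detects both loci in ≥90% of replicates at the
permutation threshold, while the null locus stays below it.  (An earlier
analytic target of ~1.6 s.d. under-accounted for the dilution from
estimating the discriminant axis on 20+20 parental specimens and was
revised during calibration.)

**Two scenario presets.**  `f2_cross_config()` (parents + F1 + 91 F2)
carries the architecture the intercross supports: two additive,
codominant loci and a marginally null modifier — no suppression term,
because an active suppressor necessarily acquires a marginal effect in
a segregating F2 (≈0.2 of the total effect for the donor-homozygous
quarter), which contradicts the modifier's observed F2 nullity.
`congenic_config()` (parents + 3 congenics + 3 bicongenics, 28 each)
carries the architecture the congenic comparisons support: suppression
0.8 of the Chr1-like effect by the donor-homozygous Chr13-like segment,
donor allele recessive at Chr1, dominant at Chr18.  The split mirrors
the central empirical point that the epistasis is invisible in the F2
and only emerges in bicongenic strains; a single fixed dominance or
suppression coefficient cannot reproduce both data sets at once.

**What the generator does not emulate.**  Real bones have asymmetric
biological variation with spatial correlation, measurement error that is
not radial-Gaussian, litter/cage effects, and — critically — shape
variation that is empirically *independent* of size.  In the generator,
genotype drives both outline geometry and area, so the size–shape
regression comes out significant on synthetic cohorts even though the
study found no such association in the real data; passing tests
therefore validate the machinery, not that real nasal-bone shape is
size-free.  Detection rates on synthetic data likewise say nothing about
power on real skulls.

## Numerical choices

- GPA: tolerance 1e-10 on consensus displacement, 100 iterations max,
  consensus initialized from the first specimen, proper rotations only
  (reflection is reserved for the symmetrization step, preventing
  accidental chirality flips).
- Fourier transform: arc-length (not index) parameterization, robust to
  uneven digitization before resampling; harmonics above the Nyquist
  limit of the point count trigger a warning, not an error.
- Truncated-series reconstruction converges ~O(1/H) at the polygon
  vertices (slope discontinuities), so exact round-trip identities are
  asserted at measured tolerances (≈2e-3 at H = n/2 for a 64-point
  ellipse), not at machine precision.
- Degenerate inputs are rejected with specific errors: zero-area
  outlines, coincident landmarks, coincident midline control points
  (undefined symmetry axis), constant phenotypes or scores, singular
  pooled covariances (advice: retain fewer PCs).
- Permutation thresholds, gamete sampling and all outline noise flow
  from one seeded generator per dataset; identical config + seed
  reproduce output files byte-for-byte (a manifest stores the seed and
  a config hash).
- Problem sizes used in the shipped analyses: 91 F2 individuals, 18–28
  per fixed-genotype group, 50 replicates for detection-rate summaries,
  1000 permutations for thresholds (400 in replicated sweeps).

## Known limitations

- Marker regression only; no pseudomarker positions between markers, no
  multiple-QTL model selection, no covariates (the design is age-matched
  single-sex).
- The dominance coefficient is a single fixed number per locus, which is
  why the F2 and congenic presets differ (see above).
- The canonical-variate solver requires a nonsingular pooled
  within-group covariance; with 15 PCs the smallest analysis groups must
  jointly carry more than 15 within-group degrees of freedom.
- TPS support covers landmark + curve records and bare coordinate
  lists; slider/semilandmark attributes and image records are out of
  scope.
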