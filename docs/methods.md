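# Methods

## Coordinate system

All statistics are computed on CIE 1976 u′v′ chromaticity; luminance is
carried through I/O but discarded by every analysis. The booth coordinates
printed for the two illuminants — (0.27, 0.53) at ~2600 K and (0.22, 0.50)
at ~4000 K — sit on the Planckian locus in u′v′ but not in CIE 1960 uv,
which fixes the interpretation of "uv" in the source measurement protocol;
a test verifies both booth chromaticities against blackbody spectra
computed from Planck's law. Fields are still named `u` and `v`, matching
the shorthand used in the experimental literature.

Spectral input is converted with the CIE 1931 2° color-matching functions,
embedded as constants at 5 nm resolution (380–780 nm) and linearly
interpolated to the measurement grid; integration is a rectangle rule on
the spectrum's own grid. Radiometer output is already discretized and none
of the downstream statistics is sensitive to quadrature refinements, so no
higher-order rule is used. Tristimulus values are scaled by K_m = 683 lm/W
so Y is in cd/m² for absolute radiance input; chromaticity is unaffected
by this scale.

## The analysis chain

**Cleaning.** Observer level: discard observers missing a chip notation on
strictly more than half their cubes, or flagged (`wrong_location`) as
systematically recording responses in the wrong slot — both judgments are
study-supplied inputs, not recomputed. Trial level: discard
indecipherable/missing notations, chips without radiometry in the matching
booth, and matches flagged as a clearly different, non-adjacent color
category by *both* independent raters. Category judgments are inputs in
real-data mode; an automated hue-sector surrogate (categories as sectors
around the booth white point; flag when chip and cube hues are more than
one sector beyond adjacency apart) exists solely so synthetic pipelines
exercise this path. Cleaning is idempotent and the report is conservative
(in = out + discarded at each level).

**Constancy index.** The reference chromaticity is the mean baseline
match, not the cube's physical chromaticity: illumination inside the
booths is spatially non-uniform and the region observers used is unknown,
so the index measures concordance between baseline and test-condition
matches (a *relative* constancy index). The constancy prediction averages
the baseline-chosen chips re-measured in the matching booth, weighted by
trials (a chip chosen by k observers counts k times) — "average match"
averages over matches, not unique chips. The canonical estimator averages
per-observer modified Brunswick ratios and reports their s.e.m. (sample sd
/ √n); the variant computed from the condition's average match is exposed
separately and equals the per-observer mean exactly, by linearity of the
projection.

**Split-half error.** Default `n_splits = 1000` random equal-as-possible
partitions with a fixed default seed; a single split is the literal
original procedure but a needlessly noisy estimator, and the partition
average converges to a well-defined functional of the data. Odd groups
differ by one; membership is uniformly random. Note a structural property
of this floor: the distance between two half-sample means has √2 times
the spread of the distance between two independent full-sample means, so
under a pure null the split-half floor sits *above* condition-vs-baseline
mean distances of equal-n data. It is reported unscaled, as defined.

**Dispersion.** Variability is the mean (not median) distance to the mean
match and is translation invariant. The ellipse fit is the direct
least-squares conic fit with the ellipse-specific constraint
(4ac − b² = 1) in the numerically stable partitioned formulation, applied
after centering and isotropic scaling — the raw normal equations are badly
conditioned at u′v′ scale (~10⁻¹). At least 5 points in general position
are required; collinear or coincident configurations raise. Palette
density counts chips inside a disc centered on the mean baseline match
with radius equal to the across-cube mean baseline variability; chips
exactly on the boundary count as inside (ties have measure zero with
measured data; a declared rule keeps tests deterministic), and a
multiplier table checks stability of conclusions across disc sizes.

**Inference.** Paired two-tailed t-tests across cubes; Pearson r with the
t-transform p; and a fixed-effects ANOVA on the complete cube ×
illumination × background table of error indices, with the
illumination × background interaction but *no* cube × factor interactions
— with one value per cell (64 observations) this leaves the 45 residual
degrees of freedom the design implies. Baseline cells carry the split-half
eI. The model is fit by OLS via statsmodels with Type II sums of squares
(equivalent to I/III here; the design is balanced, and a hand
sums-of-squares oracle cross-checks it in the tests). P-values are
uncorrected by default — the transparent choice when the test family is
ill-defined — with an optional Bonferroni multiplier.

## The synthetic experiment generator

The generator exists because neither the raw matches nor the physical
palette are published; it makes every pipeline stage testable and
parameter recovery demonstrable. It emulates:

- a 1022-chip palette in strips of 7 or 8, drawn from a Gaussian-cluster
  mixture in u′v′ (defaults: 12 clusters, sd 0.025, geometric weights
  0.85) clipped to the box u ∈ [0.14, 0.48], v ∈ [0.44, 0.58] bounding
  the measured chip cloud — commercial palettes sample color space very
  non-uniformly, and cluster weights control that density; strips group
  neighboring hues, as physical paint strips do;
- the 16 printed cube stimuli with their paired backgrounds and home
  booths, and the counterbalanced design (8 cubes per observer, 2 per
  condition, full coverage every 8 observers);
- booth-to-booth surface re-measurement via a diagonal von Kries scaling
  in Hunt–Pointer–Estévez cone space (lift u′v′ to XYZ, scale cone
  signals by the illuminant ratio, project back). Mapping the booth-A
  white point exactly to the booth-B white point is the contract; the
  specific primaries are an implementation constant. This stands in for
  physically re-measuring each chip and cube under the second lamp;
- observers parameterized by **α** (degree of illuminant adaptation:
  the internal target moves fraction α from the cube's viewing-booth
  chromaticity toward its von-Kries image in the matching booth; 1 =
  constancy, 0 = proximal matching), **β** (gain on a chip-independent
  background-contrast vector, background minus booth illuminant; default
  0 because the headline empirical finding is that background barely
  moves average matches), **σ** (isotropic bivariate Gaussian match
  noise; default 0.008 u′v′, chosen so baseline matches scatter over a
  handful of chips per cube as the real data do), and **σ_cross** (extra
  noise on cross-booth trials, default 0 — enabling it models the added
  uncertainty of representing two illuminants at once and reproduces the
  elevated illumination-condition variability seen empirically);
- discretized responding: the chosen chip minimizes u′v′ distance to the
  internal target among chips measured in the matching booth, ties broken
  by lowest chip id.

Seeding: one root seed; the palette and each observer get independent
streams by counter-based spawning, so growing `n_observers` never
reshuffles earlier observers, and identical configs produce byte-identical
output files.

What the generator does **not** model: spectral rendering and scene
geometry, luminance variation across cube faces, observer-specific biases,
appearance-vs-reflectance instruction effects, and any background
mechanism beyond the single gain β. Passing tests therefore demonstrate
that the *pipeline* is correct and well-calibrated under a minimal
observer model — not that real observers behave like the model.

## Parameter recovery and known limitations

With a dense, near-uniform palette (≈10⁴ chips) and σ = 0.004, the
pipeline's across-cube mean Brunswick ratio recovers α within 0.03 over
α ∈ {0, 0.25, 0.5, 0.75, 1.0} (100 observers). Per-cube indices carry an
additional quantization error of order (chip spacing)/‖phys‖ — a few
hundredths under the dense palette, up to ~0.1–0.2 with the realistic
1022-chip clustered palette in its sparse regions — which is a property of
discretized matching itself, not of the estimator. At fixed σ, coarser
palettes inflate measured variability, the direction behind the observed
negative density–variability correlation.

One structural caveat follows from the split-half definition above: under
a pure β = 0 null, the background-condition eI (distance between two
independent ~14-observer means) is systematically *smaller* than the
unscaled split-half floor by a factor approaching √2, and a paired t-test
across 16 cubes frequently detects this. The empirical equivalence of
background errors and split-half errors in real data is therefore not an
automatic consequence of a no-effect background; reproducing it would
require either a small genuine background perturbation or a √2-rescaled
floor, neither of which is assumed here.

Problem sizes used by the test suite (study-scale replicates at 111
observers, 20 replicates for the null-background pattern, 10⁵-draw
Monte-Carlo oracles, 800 × 100 split-half datasets) were chosen so
sampling error sits well inside each assertion's tolerance.
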