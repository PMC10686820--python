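# Methods

## Model

A sample mixed uniformly into a gel-filled, axially symmetric vessel seeds
viable cells as a homogeneous spatial Poisson process of intensity λ (the
in-gel CFU/mL).  Projected onto the vessel axis, colony positions are an
inhomogeneous Poisson process whose density is proportional to the
cross-sectional area: for a cone or square pyramid of axial length `h`,
`pdf(x) = 3x²/h³` and `cdf(x) = (x/h)³` with `x` measured from the apex in
mm; a wedge gives `2x/h²` and a cylinder `1/h`.  The total colony count is
Poisson with mean `λV`.

The estimator divides the count `N` of colonies in an axial interval by the
interval's expected probability mass and the gel volume:

    λ̂ = N / ( V · [cdf(x₂) − cdf(x₁)] ),

reported on the original-sample scale after multiplying by the embedding
dilution factor (default 100, i.e. the standard 1:100 sample-into-gel
protocol).  Axial length and volume are independent parameters throughout: a
real pipette tip is not an exact cone, and the estimator needs only `h` for
geometry and `V` for concentration.

### Counting conventions

Writing the `k` colonies nearest the tip as `x_(1) ≤ … ≤ x_(k)`:

* **interval** (default): `x₁ = x_(1)`, `x₂ = x_(k)`, and `N` counts the
  half-open interval `[x₁, x₂)`, so `N = k − 1` absent ties.  On the CDF
  scale the interval mass is a Gamma(k−1) waiting time, making the estimate
  `(k−1)λ/Gamma(k−1)`; at k = 10 about 95–96% of cones land within a factor
  of 2 of λ.
* **tip_anchored**: the interval is `[0, x_(k))` — the apex is a known point
  of the process, so anchoring there is admissible and slightly less biased
  (the denominator becomes a Gamma(k) variable; ≈97% within factor 2 at
  k = 10).  Exposed because the difference matters when comparing counting
  conventions; the default stays on the first-to-last form of the estimator
  equation.
* **full_volume**: the whole vessel, `λ̂ = N_total/V` — the exact-count
  oracle the interval modes are tested against.

Ties: colonies exactly at `x₂` are excluded by the half-open rule; a tied
first-and-last pair is a zero-mass interval and raises rather than returning
±inf.  A single colony cannot define an interval and raises with a pointer
to `full_volume` mode; an empty tip returns a flagged below-detection-limit
result carrying `dilution/V` (667 CFU/mL for 150 µL at 1:100) as an upper
bound rather than a point estimate.

The error metric throughout is the dynamic-range-aware *factor-off*
`|calculated − actual|/actual + 1`: 1 at perfection, 2 when off by the
actual value itself.  Note an underestimate can never exceed 2 on this
metric; overestimates are unbounded.

## Synthetic data

Two samplers generate colony configurations, both exact for the model above:

* the **full sampler** draws `N ~ Poisson(λV)` and positions by inverse
  transform `x = h·u^{1/3}`, plus radial coordinates uniform over the
  cross-sectional disc at each `x` (used only for rendering; the estimator is
  radially blind and tests assert this bit-for-bit);
* the **truncated sampler** emits only the `m` colonies nearest the tip as
  cumulative exponential gaps on the CDF scale — the first arrivals of the
  equivalent unit-interval Poisson process.  This keeps Monte-Carlo studies
  at 10⁷ CFU/mL (1.5 M colonies per cone) at O(m) cost, and the two samplers
  are verified against each other distributionally.

Replicates get independent RNG substreams spawned from one seed, so
perturbation studies can replay identical cones (paired design).  All
defaults mirror the standard protocol: p200 geometry (h = 36 mm,
V = 150 µL), 1:100 dilution, k = 10 colonies, 1,000 replicates per
simulated condition, densities spanning 10³–10⁷ CFU/mL.  Study sizes are the
package's own defaults chosen so each study completes in seconds; all
summary statistics quoted anywhere in the docs are computed by the tests,
the examples or `scripts/acceptance.py` at exactly these sizes.

What the generator does *not* emulate: colony growth and morphology, gel
autofluorescence or staining gradients, manufacturing imperfections of real
tips, or correlated detection failures (occlusion).  Passing tests therefore
validate the estimator and pipeline logic under the model's assumptions, not
performance on laboratory images.

## Robustness analyses

* **Missed colonies**: `n_missing` of the first `n_counted` (default 15)
  colonies are removed — uniformly at random by default; nearest-tip-first
  (worst case, it moves x₁) and farthest-first policies are available — and
  the survivor set is re-estimated.  Removing 10 of 15 keeps the mean
  factor-off ≤ 2 at every density.
* **Apex misplacement**: all positions are shifted by a signed offset
  (positive = assumed apex too far from the colonies), clipped to `[0, h]`,
  with `h` unchanged.  The alternative reading (rescaling `h`) was
  considered and not used.  A 4 mm error on 36 mm keeps the mean factor-off
  ≤ 2; high densities are most sensitive because their colonies sit closest
  to the apex, where a shift changes the local cross-section most — and the
  resulting *underestimate* asymptotes to factor-off 2 by the metric's
  construction.
* **Replicate noise**: coefficient of variation (sample sd/mean) of
  replicate estimates, computed on the linear CFU/mL scale (the
  conventional definition; the log-scale alternative was considered and
  rejected as nonstandard).  With whole-cone counts the CV is pure Poisson,
  `1/√(λV)`, shrinking with density.

## Ruler

Inverting the expected count `m·(x/h)³ = k` gives the expected position of
the k-th colony, `x_k = h(k/m)^{1/3}`, for a sample whose expected in-gel
colony number is `m = (c/D)·V`.  Concentrations with `m < k` are not
annotatable and are dropped with a warning.  "Expected k-th colony" is
implemented as this expected-count inversion; the median of the k-th order
statistic under Poisson counting (solve `P(N([0,x]) ≥ k) = ½`) is available
via a flag and differs by O(1/m).  The SVG output uses millimetre user units
with explicit physical width/height so a 100%-scale print is dimensionally
exact; simulated 10th-colony positions agree with the ticks within 5% for
`m ≥ 3k`, and nearest-tick reading of simulated tips recovers the truth
within one 4× tick step in ≥90% of cones.

## Imaging

The renderer draws the cone silhouette (background 0.85, gel 0.60, colonies
0.15 of full scale, 16-bit output), places each colony disc at its
(axial, radial) position, applies optional tilt and additive Gaussian noise,
and emits the ground truth as a JSON sidecar.  Colony radius follows the
self-limiting-size rule `r = r₀(1 + λ/d₀)^{-1/3}` (defaults r₀ = 66 µm,
d₀ = 10⁵ CFU/mL — i.e. 10 px for an isolated colony at 6.6 µm/px), a stated
stand-in for an empirically observed but mechanistically unexplained
phenomenon.  When the smallest rendered colony spans < 2 px the image
carries a resolution warning; this is how a coarse sensor (13.7 µm phone
pixels vs 6.6 µm camera pixels, both built in as optics profiles) loses the
high-density end of the dynamic range while remaining accurate wherever
colonies resolve.

Tip segmentation thresholds the silhouette against the border-estimated
background level (plain Otsu can split colony-vs-gel instead of
tip-vs-background once projected colonies cover most of a dense tip),
extracts each row's leftmost/rightmost silhouette columns with a half-pixel
edge correction, fits the two boundary lines by least squares over the
central 15–90% of the tip's extent, and takes their intersection as the apex
and their bisector's angle as the tilt.  This replaces a ridge-filter/
angle-convolution search with a direct line fit that meets the same
contract — ≤ 2 px apex and ≤ 0.5° angle error on noise-free images — with
subpixel behaviour that is easy to reason about.  Without the half-pixel
correction the integer edge columns widen the silhouette by ~1 px, which
the shallow edge-line intersection amplifies into a ~9 px apex bias.

Colony detection is multi-scale Laplacian-of-Gaussian blob search on the
colony contrast (gel level estimated as the 98th intensity percentile inside
the silhouette), restricted to an axial window selected by routine level:
whole tip, 1/2, 1/5, 1/10, or 1/20 of the axis from the apex, the last
capped at the first 30 colonies.  The five levels reinterpret a set of
size-specific routines as zoom windows — dense tips saturate in projection
except near the apex, which is exactly where the estimator needs colonies.
Intermediate window fractions are a geometric interpolation between the
stated endpoints.  A curation hook accepts add/remove coordinates in pixel
space, mirroring semi-automated use without a GUI.  Pixel-to-mm calibration
is a single scalar; lens distortion is out of scope.

## Numerical and interface choices

* Units: mm and µL internally (1 µL = 1 mm³), mL only in the final
  concentration division; results report sample-scale and gel-scale CFU/mL.
* Seeds: every stochastic entry point takes a seed; per-condition child
  seeds come from `SeedSequence` spawning and stay below 2³¹.
* Conditioning: convergence summaries at colony count k include only
  replicates with ≥ k colonies (a cone cannot contribute at a count it never
  reached); the retained count is reported per cell.
* Dilution-series fits average replicate estimates after taking log₁₀, then
  regress on log₁₀ true density by ordinary least squares; degenerate
  designs (one step, fold = 1) raise.
* Consumables: rates default to the standard protocol (15 tips/sample for
  the drop assay, 1 for the geometric assay, 96 tips/box, 25 mL of 1.5%
  agar per dish, 200 µL of 0.5% agarose per embedding); box and dish counts
  are ceilings.  Drop-assay dish amortisation has no standard value and is
  only reported when configured.  Monetary costs are out of scope.

## Known limitations

* The estimator's interval mode follows the first-to-last-colony equation;
  whether historical implementations counted the last colony (closed
  interval) is not determinable from the estimator's definition alone, so
  both conventions are exposed and their difference is quantified in tests
  instead of guessed at.
* No per-tip confidence intervals are provided (replicate CV is the noise
  measure); colony-size-based viability weighting is not modelled.
* Synthetic images validate the pipeline, not camera physics: illumination
  gradients, refraction through the tip wall, and real colony morphology are
  absent, so image-based accuracy numbers here are upper bounds on
  real-image performance.
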