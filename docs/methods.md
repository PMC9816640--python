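# Methods

This note documents the models, numerical choices, and deliberately open
design decisions behind `spindlemorph`, in the spirit of a statistical
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and coordinates

A `SpindleReconstruction` holds MT tracks (ordered 3D polylines), one or two
poles (mother/daughter centriole positions), kinetochores (with their
associated KMT track ids and sister pairing), the observer list, and
optional serial-section metadata. All coordinates are stored in nanometres;
Amira files in other units are rescaled through the label map's
`coordinate_scale_nm`. The Amira reader supports only the SpatialGraph
content subset (`VertexCoordinates`, `EdgeConnectivity`, `NumEdgePoints`,
`EdgePointCoordinates`, plus integer edge attributes); attribute naming in
deposited models varies, so the mapping from attribute values to KMT status
and fiber ids is configurable rather than hard-coded. Unlabeled tracks
default to non-KMT: KMT status requires positive kinetochore evidence.

## Geometry

**Z-correction.** Serial plastic sections collapse during imaging; stacks
are re-expanded by the factor (nominal section thickness × number of
sections) / measured total thickness, applied to z only and recorded in the
metadata. The factor is defined so that a collapsed stack (measured <
nominal total) is expanded (> 1); applying the reciprocal factor restores
the input, which the tests check.

**Polarity.** For KMTs the kinetochore-associated end is the plus end by
definition. For non-KMTs the end closer to the nearest mother centriole is
the minus end; exact ties resolve to the first endpoint and set a tie flag
rather than failing or choosing at random.

**Relative position D.** Orthogonal projection of the minus end onto the
axis from the mother centriole (D = 0) to the reference (D = 1): the
kinetochore center for KMTs, the average kinetochore position for non-KMTs.
The kinetochore center is the component-wise median of the KMT plus ends
(even counts: mean of the two central values). D is *not* clamped — values
slightly below 0 or above 1 are real geometry; they are excluded with
logged counts only when binning to [0, 1].

**Density and interaction area.** The minus-end density is a Gaussian KDE
(Scott's bandwidth by default, overridable) evaluated on a grid padded by
five bandwidths so its trapezoid integral over the grid is ≈ 1; the peak is
the grid argmax. The pole "interaction area" is either the fixed default
D < 0.2 or derived from the density: a Gaussian is fitted to the
pole-proximal peak (the contiguous region above 10% of the peak height) and
the bound taken as μ + 2·HWHM with HWHM = σ√(2 ln 2). Whether the published
half-width refers to a fitted Gaussian or the raw KDE peak is not
documented; the fitted version is the default because it is insensitive to
grid resolution.

**Other.** Tortuosity is polyline arc length over end-to-end distance, on
the polyline as given (no spline re-fitting). Angles are computed between
explicit landmark rays; automatic landmark detection is out of scope.
Endpoint-Z QC counts track endpoints per section interval and reports the
coefficient of variation (flag threshold 0.5 by default; a perfectly
stitched stack should have near-uniform endpoint density in Z).

## The morphology model

Classified minus ends (undefined labels excluded from the binomial
denominator, since the outcome is modeled as binary) are counted per
(distance bin, observer) in 16 equal-width bins over [0, 1]; bins are
left-closed/right-open with the last bin closed so D = 1 is not dropped.
The model is

    y[b,o] ~ Binomial(n[b,o], p[b,o]),
    logit p[b,o] = Σ_k B_k(mid_b) β_k + u_o,   u_o ~ N(0, σ_u²),

with a cubic b-spline basis B ("third-order" is read as degree 3; the
degree is configurable because order/degree conventions differ), 5 equally
spaced interior knots over the bin-midpoint range and boundary knots
repeated degree + 1 times, giving n_interior + degree + 1 basis functions.
Priors are weakly informative: β_k ~ N(0, 2.5), σ_u ~ HalfNormal(1). These
and the knot layout are configurable; nothing in the published analyses
pins them down, and the defaults are chosen so that a flat 50% curve is
well inside the prior bulk.

**Sampling.** The sampler explores only the β space: the per-observer
offsets are integrated out by 15-node Gauss–Hermite quadrature (one 1-D
integral per observer) and their scale σ_u by 10-node Gauss–Legendre
quadrature on the prior-CDF scale. This marginalization removes the
funnel-shaped geometry that makes the joint space slow to traverse, and
leaves a posterior close enough to Gaussian that an ensemble sampler mixes
in a few steps. Sampling proceeds in two stages with `emcee`: a
differential-evolution warmup (default 500 steps, 32 walkers) to locate and
scale the posterior, then production steps (default 2500, first 250
discarded, thinned by 8) mixing an independence proposal — a multivariate t
(df 7, covariance 1.3× the warmup covariance) — with DE moves. The
split-chain R-hat across walkers is computed with `arviz` and a warning is
emitted above 1.01. Posterior draws of σ_u are reconstructed per β draw by
inverse-CDF sampling of the conditional on the quadrature grid, and
observer offsets u_o by grid inverse-CDF of their 1-D conditionals; both
are reported but do not feed back into the curve. With a single observer
the offset is not identifiable separately from the spline intercept and
the random effect is dropped automatically, which also makes the
single-bin posterior exactly comparable to 1-D quadrature of
prior × binomial likelihood (a test asserts agreement within 0.01 in mean
and sd).

**Summaries.** The population curve uses u = 0. The pole-region summary
averages the population-level p over in-region bin midpoints weighted by
each bin's classified-end count (matching "proportion of ends" semantics;
an unweighted option exists). Condition contrasts are computed from
independently fitted posteriors by pairing draws index-wise and
differencing log2 odds on the logit scale (so p ∈ {0, 1} cannot occur);
the contrast is antisymmetric under swapping conditions by construction.

**k-fiber clustering LRT.** Per-end open/closed outcomes, distance-bin
fixed effects (8 bins by default), with vs. without a fiber-level random
intercept fitted by maximum likelihood (20-node Gauss–Hermite marginal per
fiber, two σ starting points to avoid the boundary local optimum). Because
the null puts σ on the parameter-space boundary, the LRT statistic is
floored at 0 and referred to the ½χ²₀ + ½χ²₁ mixture. Complete separation
in a bin is raised as an error, never silently absorbed.

**Interaction test.** Binomial GLM of the open/closed outcome on MT class,
condition, and their product, restricted to the pole region; the
interaction coefficient is reported on the *natural*-log-odds scale (the
published interaction estimate uses log, unlike the log2 contrasts) with
its Wald p-value. Pure cells are rejected as separation.

## Synthetic spindle generator

The generator emulates the statistical structure the analysis assumes, not
spindle biophysics: two poles 10 µm apart on the x-axis (any positive
separation works since D is normalized; 10 µm is a typical HeLa metaphase
scale), mother/daughter centrioles 0.25 µm apart, sister-kinetochore pairs
on a 1.5 µm metaphase-plate disk with separations ~ N(1.06, 0.21²) µm,
zero-truncated-Poisson KMT counts per fiber (a fiber with zero KMTs is not
a fiber), KMT minus-end positions from a mixture of a pole-proximal
normal (σ_D = 0.04, weight 0.7) and a uniform background, quadratic
Bézier-bowed polylines whose bow amplitude is solved by bisection to hit a
target tortuosity (default 1.05), and non-KMTs spanning random axis
intervals. Morphology labels are drawn per observer from
expit(logit p_open(D) + u_o) with configurable offsets (default ±0.3) and
an undefined rate (default 0.10); KMT plus ends at kinetochores are always
open. Everything is reproducible from the seed, and the ground-truth object
records the generating curve, offsets, per-end positions and counts.

Scenario presets carry the published scale of the two conditions:
control-like (226 k-fibers × 9.19 KMTs/fiber ≈ 2100 classified KMT minus
ends, minus-end peak at D = 0.03, truth curve ≈ 53% open at the peak) and
siMCRS1-like (106 × 7.27, peak at 0.07, ≈ 75% open), plus a "null" preset
identical to control-like for type-I-error studies. The truth curves are
logistic in D; their parameters were fixed once from the targeted region
proportions. What the generator does *not* emulate: image-level noise,
segmentation/stitching errors, spatially correlated misclassification,
k-fiber-level morphology clustering (absent by design, which is what the
LRT null tests), or class-specific truth curves within a condition — so
passing recovery tests demonstrate correctness of the inference machinery
on data satisfying the model's assumptions, not robustness to annotation
artifacts in real tomograms.

## Problem sizes in tests and the acceptance script

Simulation studies in the test suite use sizes chosen to give stable
operating characteristics at desk scale: parameter recovery at 16 bins ×
300 ends × 2 observers; posterior-contrast calibration over 100 null
replicate pairs (reduced sampler settings: 24 walkers, 150 warmup + 250
production steps); LRT operating characteristics over 100 replicates of 50
fibers × 10 ends; simulation-based calibration over 200 prior draws of the
single-bin model. The acceptance script runs the two presets at their full
published scale with default sampler settings.

## Known limitations

- The observer effect is exchangeable-normal; systematic observer × distance
  interactions are not modeled.
- Independent fits per condition (matching the published contrast
  presentation) forgo partial pooling across conditions.
- The quadrature marginalization assumes the per-observer conditional is
  well captured by 15 Hermite nodes; extreme σ_u (≫ 2 on the logit scale)
  would need more nodes.
- The Amira reader covers the SpatialGraph ASCII dialect only; binary
  AmiraMesh files must be converted upstream.
- `kfiber_random_effect_lrt` treats distance through bin indicators, not
  the spline, mirroring the model-comparison purpose rather than reusing
  the Bayesian fit.
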