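# Methods

`vesselmorph` quantifies posterior-pole retinal vascular morphology from
binary segmentation masks — the vessel mask and the optic-disc (OD) mask of
one eye — and compares the resulting per-eye statistics between clinical
groups. A synthetic vascular-tree generator with exact ground truth stands
in for patient images, so every stage of the pipeline is validated by
parameter recovery rather than by eyeballing.

## Analysis region and frame selection

All metrics are computed inside a concentric annulus anchored on the optic
disc. The OD center and radius are those of the **minimum enclosing circle
(MEC)** of the OD mask's foreground pixel centers, computed exactly with a
Welzl-style incremental construction applied to the convex hull (points are
deduplicated and sorted first, so the result is independent of input
order). The analysis ring spans radii `[2 r_od, 4 r_od)` around the MEC
center, half-open so that every pixel belongs to exactly one of the
disc-adjacent / ring / peripheral zones. The ring's pixel count is an exact
enumeration of in-image pixel centers, and both it and the MEC are checked
against brute-force oracles in the test suite.

Before analysis, each frame passes a centering gate: the OD center must lie
within one quarter of the image width of the image center (inclusive
boundary, to avoid float-equality fragility). For a W×H raster the image
center is `((W-1)/2, (H-1)/2)` in pixel-center coordinates. Failed frames
are recorded with `passed = False` and a reason, never silently dropped.
The MEC center is used consistently for both gating and the ring; a mask
centroid would be an equally defensible OD-center definition, but a single
convention keeps the geometry coherent.

## Centerline graph

The ring-clipped vessel mask is thinned to a one-pixel, 8-connected
skeleton (`skimage.morphology.skeletonize`), clipping **before** thinning
so boundary-truncated branches keep their raster length. Skeleton pixels
with a neighbor count other than two become node pixels; adjacent node
pixels merge into clusters positioned at their centroid. Degree-1 nodes
are endpoints, degree-3 nodes bifurcations, degree ≥ 4 crossings (two
vessels overlapping in raster space — excluded from angle measurement,
since a branching angle is only defined at a bifurcation). Chains of
degree-2 pixels become edges carrying the ordered centerline; isolated
cycles get one artificial anchor node. Spur edges shorter than 10 px that
end in an endpoint are pruned iteratively, and degree-2 nodes left behind
are merged by concatenating their edges (bridging through the node cluster
so paths stay 8-connected); the operation is idempotent. The 10 px default
suppresses thinning barbs on full-width vessels without deleting real
terminal twigs at the generator's scale.

## The four statistics

**Bifurcation angle.** At each degree-3 node, each incident branch
direction is the total-least-squares line direction of the centerline run
covering arc lengths 4–24 px from the node, oriented away from it. The
first 4 px are skipped because thinning the union of full-width vessels
displaces the skeleton inside the junction zone; with the skip, recovered
cohort means are within ~1 degree of truth where without it they were
biased by up to +4 degrees at 5 px calibers. The parent branch is the one
whose direction best aligns with the unit vector from the node toward the
OD center — at the posterior pole, flow geometry points parent vessels
back toward the disc — and the reported angle separates the two remaining
(daughter) directions. Per eye, angles are averaged unweighted over
bifurcations; zero bifurcations yield a missing value, not zero.

**Vessel density.** Foreground fraction of the ring, in percent. The
denominator defaults to the ring area, which makes the metric comparable
across disc sizes; a config switch (`density_denominator="image_area"`)
divides by the full raster area instead for the literal whole-image
reading.

**Fractal dimension.** Box counting on the skeleton (a config switch
allows the full-width mask): for each dyadic box size ε from 2 px up to a
quarter of the ring bounding-box short side, N(ε) counts occupied ε×ε
cells on a grid anchored at the bounding-box origin; FD is minus the OLS
slope of log N(ε) against log ε. No grid-offset averaging — deterministic
and simple. Validated on a straight line (FD ≈ 1), a filled block
(FD ≈ 2), and the Sierpinski triangle (FD ≈ log 3 / log 2 within 0.05,
with convergence confirmed on the 1024² construction).

**Tortuosity.** Hart's arc-length-normalized total squared curvature,
τ = (1/L)∫κ² ds, reported per eye as the length-weighted mean over
segments of at least 30 px, in units of 10⁻³ px⁻². Curvature estimation on
raster centerlines is the numerically delicate step: a naive
finite-difference κ on the pixel chain is dominated by stair-step noise
(orders of magnitude too large on shallow arcs). The estimator therefore
resamples the path at 1 px arc steps, smooths with a moving average of 9
samples applied twice (a triangular kernel), and takes κ at each sample as
the inverse circumradius of the circle through the points k samples to
either side, with k = 12 shrinking to a floor of 4 near the ends. The
three-point circumradius is exact on circular arcs at *any* spacing, so
the wide span buys noise suppression at essentially no bias on smooth
vessels. Measured accuracy: semicircles of radius 25–100 px within ~1%,
straight lines exactly 0, generator sinusoids within ~3% on average
(placement-randomized ensembles). The absolute 10⁻³ scale is **not**
comparable to values computed on other pixel grids or with other smoothing
choices; only orderings and ratios are meaningful across pipelines.

## Group statistics

Per metric: group mean ± SD (n−1 denominator), omnibus fixed-effects
one-way ANOVA (F from sums of squares; p from the upper F tail via the
regularized incomplete beta function), and pairwise Welch t-tests with
Holm adjustment as the post-hoc procedure — Welch avoids assuming equal
variances, Holm controls the family-wise error rate without studentized-
range machinery. Pearson's χ² (p via the regularized upper incomplete
gamma) is provided for categorical tables such as QC pass rates. Missing
metric values are excluded pairwise per metric. Calibration: the ANOVA's
type-I error over 1,000 null simulations sits inside the binomial 95% band
around 5%, the two-group F equals t² to 1e-9, and the 2×2 χ² matches its
closed form to 1e-9.

## Synthetic data generator

Each synthetic eye is a binary recursive bifurcation tree radiating from
the OD rim: no trifurcations, no anastomoses (raster crossings between
independent subtrees still occur and are what the graph stage must
tolerate). Defaults describe a 1600×1200 px frame with the disc at the
center: OD radius 50 px, 6 roots, 3 bifurcation levels, segment chords of
120 px ± 10%, branching angle Normal(60°, 5°) truncated to (10°, 170°),
calibers tapering geometrically from 3 px by 0.8 per level (floor 1 px),
rasterized by dilating ≤ 0.5 px-sampled centerlines with a disc element.

Waviness is a sinusoidal displacement normal to the chord with an integer
number of half-waves (zero at both endpoints, so segments join without
jumps); the default amplitude is 2.5 px at a nominal 80 px wavelength,
giving effective wavelengths of 72–88 px after half-wave rounding — the
regime where the tortuosity estimator was verified unbiased. Each
segment's true tortuosity is computed by dense quadrature of the analytic
sinusoid (`analytic_tortuosity_of_sinusoid`), an oracle independent of the
pipeline's estimator. Daughter *starting tangents* are the parent
direction rotated by ±θ/2 (the chord is counter-rotated to absorb the
sinusoid's initial slope), which makes the truth angle the locally
observable quantity; defining daughters by their chords instead leaves the
truth partially unobservable in raster at plausible waviness and biases
narrow-angle recovery by several degrees. Truth tables record every
bifurcation angle, every centerline polyline, per-segment analytic
tortuosity, and the exact vessel pixel count.

What the generator does **not** emulate: photoreceptor/choroidal texture,
illumination artifacts, segmentation errors (broken or hallucinated
vessels), artery/vein distinction, caliber pulsation, and real biological
branching statistics beyond the controlled means and spreads. Passing
recovery tests therefore demonstrates the correctness of the measurement
chain on clean masks, not robustness to segmentation noise.

## The comparison cohort

The three-group cohort (`vesselmorph.cohorts.three_group_specs`, 50
eyes/group) mirrors the qualitative clinical pattern for retinopathy of
prematurity (ROP), familial exudative vitreoretinopathy (FEVR) and healthy
full-term controls: branching-angle means 39.5 / 37.4 / 39.4 degrees
(lowest in FEVR, whose vitreoretinal traction straightens and narrows
branching), and waviness amplitudes 1.0 / 0.6 / 0.8 px (ROP's plus-
disease-like tortuosity highest, FEVR's stiff vessels lowest). Eight roots
put ~8 measurable bifurcations in each ring, and the within-eye angle
spread is 3°, so a per-eye angle mean has a standard error near 2° — the
scale needed for a 2° group effect to be detectable at 50 eyes/group.
Angle-measurement noise grows with waviness slope (per-bifurcation SD ≈ 5°
at amplitude 1.0 vs ≈ 19° at 3.5), which is why the cohort sits at mild
waviness: at plus-disease-scale waviness the same 2° effect would need
several hundred eyes per group, as in clinical studies. Measured angle
bias was verified uniform across the three amplitudes (+0.4 to +0.5°), so
the ROP-vs-healthy contrast stays null as designed.

## Numerical conventions and degenerate inputs

Coordinates are 0-based (x right, y down) with pixel centers at integers;
diagonal skeleton steps count √2 toward arc length. Empty OD masks,
degenerate (radius-0) MECs, rings outside the image, zero bifurcations,
and paths too short for curvature estimation all produce flagged missing
values at the record level; only I/O failures raise. Determinism: equal
seeds give bitwise-equal masks, truth, and metrics; per-eye seeds derive
from the cohort seed via `numpy.random.SeedSequence`.

## Known limitations

- Tortuosity and angle estimates carry raster-scale noise floors; vessels
  shorter than ~30 px contribute no tortuosity, and eye-level tortuosity
  on rasterized trees runs a few percent above the analytic truth.
- Dense or strongly wavy trees produce raster crossings whose thinning
  artifacts can masquerade as bifurcation pairs; at the cohort's waviness
  this affects well under 5% of nodes, but at amplitudes ≥ 4 px it
  dominates the angle distribution's tails.
- The FD of a ring-clipped skeleton (~0.91 here) depends on the box-size
  range and the ring's extent; values are comparable within a pipeline,
  not across studies.
- Eyes are treated as independent units; no within-patient correlation
  structure is modeled.
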