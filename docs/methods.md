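# Methods

This note records the models, conventions and numerical choices behind
`cellpol`, and what the synthetic benchmark does and does not establish
about real microscopy data.

## Coordinate conventions

Pixel coordinates are 0-based with pixel centres at integer (x, y); x is
the column index, y the row index. Raster images store row 0 at the top,
so the y-axis points *down*; all angular features therefore carry a sign
σ ∈ {+1, −1} (default −1) that converts to a conventional y-up frame.
Directed angles are reported in degrees [0, 360), axial angles in
[0, 180); internally everything is radians. Missing features are NaN /
empty CSV cells, never 0 — an isotropic shape has *no* orientation, and
coincident centroids have *no* polarity; substituting 0° would fabricate
collective signal.

## Image moments and shape

All shape and polarity features derive from raw and central moments
m_ij = Σ x^i y^j I(x, y), μ_ij = Σ (x−x̄)^i (y−ȳ)^j I(x, y), computed up
to order 3 (no feature needs more). Orientation is

φ = σ·½·atan2(2μ₁₁, μ₂₀ − μ₀₂) (mod π).

The atan2 argument order matters: with the second argument μ₂₀ − μ₀₂ a
horizontal bar yields φ = 0° and a rotation-recovery oracle (ellipses
rasterised at known angles) is reproduced to < 0.15°; the mirrored
convention fails that oracle, so this one is fixed here and validated in
the test suite rather than assumed. Axis lengths are the full axes
4√λ₁, 4√λ₂ of the intensity-equivalent ellipse (eigenvalues of the
normalised second-moment matrix); LWR is their ratio. Whether elongation
should use equivalent-ellipse axes or bounding measures is genuinely open;
equivalent-ellipse axes were chosen because they are moment-consistent
with the orientation definition and rotation-invariant to < 1% on rasters.

Perimeter uses the 4-direction Crofton estimator
(`skimage.measure.perimeter_crofton`). Contour-step estimators — even with
√2-weighted diagonals — overestimate curved boundaries by ≈ 5%, which
pushes the circularity of a 20 px-radius disc down to 0.91; the Crofton
estimator gives 0.97 on the same disc. Circularity is clipped to ≤ 1.

The cue-referenced symmetry score splits a cell by the line through its
area centroid perpendicular to the cue, reflects the front half in
continuous coordinates, resamples to the nearest pixel, and takes the IoU
with the rear half. Pixels whose centres lie on the split line (projection
|t| ≤ 1e−9) belong to neither half — this keeps the score exactly
symmetric under cue reversal and exact (1.0) for odd-width mirror-symmetric
shapes. Nearest-pixel resampling is deterministic; sub-pixel resampling
would change scores by < 0.02 on cell-sized masks.

## Polarity features

Directed polarity is the bearing from a rear to a front centroid:
nucleus→organelle (Golgi), cell centre→nucleus, cell centre→intensity
centroid of a marker. The organelle "front" centroid is intensity-weighted
over the organelle mask by default (a binary-centroid switch exists); for
the compact blobs that Golgi segmentation produces the difference is below
raster noise, but weighting is the more faithful reading of a
centre-of-mass definition.

The cue directional intensity ratio uses the *shape* centroid of the cell
(intensity-independent) to split the cell into half-planes along the cue
unit vector v̂ = (cos α_p, σ·sin α_p):

s_r = (Σ_cell I − 2 Σ_rear I) / Σ_cell I = 1 − 2·I_rear/I_cell.

Pixels with exactly zero projection are assigned to the *front* half; the
tie set is measure-zero for generic centroids and the rule makes
s_r(α_p + 180°) = −s_r(α_p) exact up to that set.

Note an effect that is easy to misread as a bug: for a *linear* intensity
gradient with direction ĝ inside a cell of second-moment tensor Σ, the
intensity-weighted centroid shifts along Σĝ, not ĝ. Elongated cells
therefore rotate the marker-polarity bearing toward their long axis. The
synthetic ground truth stores this analytically expected bearing
(`marker_polarity_expected_deg`) next to the generative gradient bearing,
and recovery is tested against the former.

## Intensity compartments

Cytosol is the strict complement of the nucleus within the cell, so
total(cell) = total(nucleus) + total(cytosol) holds exactly and is
asserted per cell. The membrane band (dilated cell contour, same
construction as the junction interface) is a separate readout that
overlaps the cytosol; treating it as a third partition element would make
the readouts depend on band thickness in a non-obvious way. The
nucleus/cytosol ratio uses mean intensities by default (a totals-based
switch exists): a concentration ratio is comparable across cells of
different size, a totals ratio is not.

## Junction morphometrics

The interface region is the one-pixel inner contour of the cell mask
dilated by a disc of radius `junction_thickness_px` (the *single*
parameter of the junction analysis), clipped only at image bounds — the
band deliberately straddles the boundary and may overlap a neighbour's
band, because junction protein lives on both sides of a shared boundary.
Dilation by a disc is exactly the set of pixels within Euclidean distance
t of the contour, which an independent distance-transform oracle confirms
pixel-for-pixel.

Otsu's threshold is computed per cell on the intensity histogram
restricted to that cell's interface region, with 256 bins between the
region minimum and maximum (Otsu outcomes depend on binning, so the
dialect is fixed and documented; an image-global option exists for
cross-cell comparability). Protein area is the set of region pixels at or
above the threshold; occupancy = protein/interface area; intensity per
interface area and cluster density are means over region and protein area
respectively, so cluster density ≥ intensity per interface area whenever
protein area is nonempty. A constant-intensity region leaves the
two-class split undefined: occupancy is reported missing, the mean is
still reported.

## Circular statistics

R, S = 1 − R, ᾱ and V = R·cos(ᾱ − α_p) follow the standard resultant
construction; axial samples are doubled (θ = 2φ), summarised, and the
mean halved. V = cR, |V| ≤ R and S = 1 − R are identities and are tested
as exact (1e−12), not approximate.

Confidence intervals for the mean direction use the large-sample circular
dispersion interval ᾱ ± asin(z·√(δ̂/n)), δ̂ = (1 − ρ̂₂)/(2R̄²), when
n ≥ 25 and the asin argument is < 1; otherwise a seeded percentile
bootstrap (B = 2000) of the circular mean with deviations wrapped around
ᾱ. Both constructions are cross-checked against each other (agreement
< 2° at n = 1000, κ = 4) and the dispersion interval achieves 94–95%
empirical coverage at nominal 95% in simulation. R below 1e−9 leaves the
mean and its CI undefined (the CI is the full circle).

Tests: Rayleigh uses Z = nR̄² with the standard two-term series
correction; the V-test statistic is u = V√(2n) with a one-sided normal
p-value; Watson's U² uses the small-sample modification and the
alternating exponential series (clamped to p = 1 when the modified
statistic is ≤ 0, where the series diverges and uniformity plainly cannot
be rejected); Rao's spacing statistic U = ½Σ|T_i − λ| is referred to a
seeded Monte-Carlo null of 10 000 uniform samples, cached per sample
size — published critical-value tables differ between editions, a
simulated null is reproducible and its resolution is explicit. Ties
produce zero spacings and blunt Rao's sensitivity; that is a property of
the statistic, not an error. Simulated type-I errors at n = 100 are
0.04–0.06 for all four tests.

These tests are computed *per image*: cells within a monolayer are
spatially correlated, so pooling single cells across images would
overstate evidence. Across conditions, the per-image indices (R, V, mean
ratios) are compared with bootstrap-coupled estimation: mean difference
with a seeded percentile CI (BCa optional); the percentile flavour is the
default because it is the simplest to validate (93–97% empirical coverage
at n = 50 per group). The V-test reference is the *expected polarisation*
direction, which for nucleus→Golgi polarity is cue + 180° (the organelle
relocates upstream); the per-feature offsets are explicit in the summary
writer and overridable.

Correlations: Mardia's circular–linear r (with n·r² ~ χ²(2) under the
null) and the Jammalamadaka–SenGupta circular–circular ρ. Which
circular–circular variant a given analysis app uses is rarely printed;
the JS ρ is the default here because it is the one with a clean
sine-moment interpretation.

## Segmentation and matching

Deep-learning segmenters are adapters selected by name and are not
bundled; requesting an unregistered backend raises immediately rather
than silently falling back. The built-in classical backend thresholds
nuclei by Otsu (4-connected components, ≥ 20 px) and recovers cell bodies
by marker-controlled watershed *on the junction channel as the elevation
map* — junction signal is bright on boundaries, so basins are the dark
cell interiors. On the synthetic near-confluent benchmark it reaches mean
IoU ≈ 0.92.

Golgi instances come from a global Otsu on the organelle channel with
labels inherited from the cell mask beneath each positive pixel (blobs
straddling a boundary are split). Each nucleus is assigned to the cell
covering the majority of its area (ties to the lower label —
deterministic and order-independent); cells with zero or several nuclei
are dropped with a logged reason, as are border-touching cells by default
(truncated masks bias every shape and polarity feature). Retained +
dropped counts reconcile exactly and are logged.

## Synthetic data: what it emulates, and what it does not

The generator lays one elliptical cell per site of a jittered grid,
clipped to the Voronoi region of its seed — non-overlap is guaranteed by
construction, and the feasibility check (semi-major ≤ 0.45·spacing,
jitter bounded) makes the Voronoi clip a no-op, so realised shapes match
their generative parameters. Per cell: a displaced nuclear disc, a
compact organelle disc placed along a sampled bearing at an adaptively
capped distance (the bearing, which is what recovery tests check, is
never altered — only the distance shrinks to stay inside the cell), and a
marker that is uniform, a linear gradient, or a nucleus/cytosol ratio
field. The junction channel is a Bernoulli(q) mixture of bright/low
pixels inside a band of width w around all cell contours, so measured
interface occupancy at thickness w estimates q. Gaussian noise (sd 5 on
backgrounds of 20–50 and signals of 200–1000) is added everywhere.

Default study conditions: 768×768 px, 49 cells (≈ 110 px spacing,
endothelial-scale at ~0.3 µm/px), semi-major 0.30–0.42 of spacing, LWR
1.4–2.6, nucleus radius 0.45 of the semi-minor axis, organelle radius
4 px, junction band width 3 px with bright fraction 0.5, noise sd 5.
These are a stylised confluent monolayer, not microscopy: no point-spread
function, no shot noise, no intensity vignetting, no segmentation errors,
no touching/overlapping nuclei, and cells are convex. Passing recovery
tests therefore establishes that the *feature definitions and their
implementation* are correct and unbiased on known geometry — not that
extraction is robust to real segmentation noise, which is bounded by the
quality of the upstream masks.

Recovery on these conditions: orientation < 0.4°, organelle/nucleus
bearings < 2°, LWR < 0.5% relative, marker bearing < 0.5° against the
shape-corrected expectation, occupancy within 0.004 of q.

## Determinism

Every stochastic step (von Mises sampling, bootstrap resampling,
Monte-Carlo nulls, synthetic noise) takes an explicit seed through
`numpy.random.default_rng`; re-running with an identical configuration
and seed reproduces every CSV byte-for-byte, and each output carries the
package version, seed and a hash of the resolved configuration in its
header line.

## Problem sizes

The validation suite works at deliberately small scale so it runs on a
laptop in well under a minute per module: ≤ 15×15 patches for the moment
oracle (200 patches), 181×181 ellipse rasters, 49–50-cell monolayers at
768² or 16-cell monolayers at 384², 2000 replicates for test calibration,
1000 replicates (B = 1000) for bootstrap coverage. The collective
recovery tolerance of 0.05 on R at 50 cells absorbs both extraction error
(< 0.02) and the sampling noise of a 50-draw von Mises sample
(sd ≈ 0.027), so occasional seeds land near the boundary by sampling
alone; extraction fidelity itself is tested separately against the
generative sample rather than the theoretical Bessel ratio.
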