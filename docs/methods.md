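# Methods

## Persistence on pixel grids

Images are treated as vertex-weighted Freudenthal triangulations: one
vertex per pixel, edges between orthogonal neighbours and the
upper-left/lower-right diagonal pair of every unit cell, and the two
triangles inside each cell. Every edge/face carries the minimum of its
incident pixel intensities (upper-star rule), so a simplex enters the
descending superlevel sweep exactly when its limiting pixel does. The
induced pixel neighbourhood has six neighbours; local maxima and all
connectivity statements below refer to it.

**Degree 0** is computed by a single union-find pass over pixels in
descending intensity (ties broken by row-major order). A component is
born when a pixel has no brighter neighbour (a local maximum) and dies,
per the elder rule, when it merges into a component with an older birth;
the death value is the intensity of the merging pixel. The globally
maximal component never merges; it is assigned death = the global
minimum intensity so that every class has finite persistence and the
k-means significance step never sees infinities.

**Degree 1** uses planar duality: holes of the superlevel complex at
threshold *t* correspond one-to-one to connected components of the
complementary pixel set {intensity < *t*} (same 6-neighbourhood) that do
not touch the image boundary. The implementation therefore runs
union-find over pixels in ascending intensity with a virtual "outside"
node attached to every boundary pixel: when a complement component is
absorbed into an older one (or into the outside), the absorbed
component is an interior hole, born at the absorbing pixel's intensity
and dying at its own minimum pixel — which is also its reported locus.
The image boundary is not closed off, so holes touching the boundary do
not exist; 1-D and 2-pixel-wide images have no holes. Both degrees are
verified in the test suite against a brute-force oracle that relabels
every threshold's superlevel/sublevel sets from scratch.

The `b`/`d` labelling for holes follows the sweep direction (birth at
the higher threshold); only the persistence |b − d| and the
interior-minimum locus are contractual, since libraries differ in their
endpoint conventions for superlevel filtrations.

## Detection

Preprocessing min-max normalises the image to [0, 1], adds zero-mean
Gaussian uniqueness noise (variance 0.01 by default), then applies a
square uniform (box) filter of odd width `round(feature_size /
pixel_size)` (ties promoted to the next odd width; reflect padding).
Adding the noise *before* smoothing is a deliberate choice: the box
filter attenuates its standard deviation by the kernel width (0.1 →
~0.014 at the 0.3 µm scale on 0.05 µm pixels), so the perturbation stays
insignificant for the persistence analysis, while pixel values remain
pairwise distinct almost surely (they are redrawn on collision), giving
every feature a unique locus pixel. Adding variance-0.01 noise *after*
smoothing instead would inject 10% of the dynamic range as white noise
and drown the significance clustering; with noise at that strength the
detector degenerates to near-total false discovery.

Significance is two-cluster k-means on the 1-D persistence values,
solved exactly: the optimal k = 2 clustering of scalars is the
contiguous split of the sorted values minimising the within-cluster sum
of squares, found by exhaustive scan (deterministic, no initialisation
sensitivity). The higher-mean cluster is significant unless its mean
falls below `significance_floor` (default 0.05) of the normalised
image's unit dynamic range; a constant image has no dynamic range and
returns no features. The floor is anchored to the *input* image's range
rather than the preprocessed one because a featureless input yields a
preprocessed image that is pure uniqueness noise, whose own range would
always clear a relative floor.

Podosomes are significant degree-0 features of the podosome-scale
image (default 0.3 µm); site candidates are significant degree-1 holes
of the site-scale image (default 1.5 µm; coarser smoothing makes hole
detection robust to the complicated actin topology between sites).
Detections are reported at pixel centres: x = (col + 0.5)·pixel_size,
y = (row + 0.5)·pixel_size, origin at the top-left corner.

Refinement iterates to a fixed point (at most `max_refine_iterations`,
default 10): assign each podosome to its nearest site centre (ties to
the lowest site index), drop podosomes farther than
`max_podosome_site_distance` from their site, drop sites with fewer than
`min_podosomes_per_site` (default 3) members together with their
orphaned podosomes, and re-centre every surviving site at the arithmetic
mean of its members. Dropped detections are never re-admitted, so the
iteration is a contraction. The distance cut defaults to 2.7 µm
(1.5 × the ring radius): a hole locus is the *minimum* pixel of the
depleted disk interior and can sit several hundred nm off the ring
centre, so the cut must cover ring radius plus that eccentricity;
2.25 µm (1.5 × the site feature size) clips far-side ring podosomes
before re-centering converges. Both the cut and the floor are exposed
in `DetectionParams`.

## Morphometry

Stacks are calibrated in µm laterally and nm axially (typically z =
0–450 nm in 10 nm steps). Line scans sample bilinearly at pixel_size/2
steps along the line through the podosome and the site centre (d < 0
toward the centre); out-of-bounds samples are NaN and excluded from
means, with a warning. Radial averaging takes, per z and per radius bin
centre (bin width = z-step, default 10 nm, so the heatmap is nearly
isotropic in display units), the mean of bilinear samples over a dense
uniform set of angles (at least 32, and enough that the arc step is half
a pixel); tests verify agreement with direct distance-binned pixel
means.

The contour smooths the heatmap with a Gaussian of σ = 1 grid cell (the
variance-1 kernel is interpreted in grid cells, since no physical unit
is attached to it) and thresholds at the mean smoothed intensity over
all cells with r ≤ 350 nm. The core profile is the mean over r ≤ 100 nm
per z; the network profile over 400–600 nm. Peaks are local maxima with
prominence ≥ 10% of the profile maximum (configurable — this is what
makes weak features "not always detected"), refined by parabolic
interpolation; FWHMs interpolate the half-max crossings linearly. The
two most prominent core maxima are the cores (upper = larger z); the
neck is the core-profile minimum between them; a single detected core
counts as the upper core, with lower core and neck absent. Network
peaks are classified below/above the inter-network trough (the neck z,
or the grid midpoint, splits a lone peak). Half-max radii are computed
for the cores only, from the heatmap row interpolated at the peak z.

Height is the z-extent of the contour's connected component containing
the heatmap maximum, so detached background blobs cannot inflate it.
Protrusion length is the lower network's lower FWHM crossing minus the
bottom z of that same component, floored at 0 (only non-negative
protrusions are meaningful). All internal values keep full precision;
rounding to the nearest 10 nm — the axial resolution of the source
modality — happens only in `PodosomeMorphology.rounded()` and the CSV
reporting layer.

## Site profiles

Radial profiles are annulus means with Δr = one pixel. Edge-type
channels are fit with a four-parameter logistic base + amp / (1 +
exp((r − r₀)/s)) by unweighted least squares (initialised from the
profile extremes and the half-amplitude crossing; r₀ bounded to the
data range); r₀ is the reported inflection radius and the amplitude
sign encodes falling (amp > 0) versus rising edges. Ring metrics take,
on each side of the podosome (d < 0 inner, d > 0 outer), the highest
local maximum passing the 10% prominence rule, with parabolically
refined positions and widths at half prominence — making the metrics
invariant to constant baselines and positive scaling. The peak-to-peak
distance is the sum of the two peak distances. Metrics are extracted
per podosome and then summarised as distributions (the box/whisker
helper in `podoscope.stats`), not extracted from averaged scans.

## Synthetic scenes

The generator emulates frustrated phagocytosis on IgG disks. A 2-D
field (default 20 × 20 µm, 0.05 µm pixels) contains 4–8 sites, each a
ring of 6–10 Gaussian puncta (0.3 µm FWHM, unit amplitude) at 1.8 µm
radius with ≤ 0.1 µm positional jitter; distractor puncta (5% of the
podosome count) are placed at least 3 µm from any site centre. The
background is a cortical-actin plateau (offset 0.35 of the spot
amplitude) with a smoothed random texture (SD 0.10, 1 µm correlation
length) and a 70% smooth-edged depletion over the ~3 µm disk — the
actin hole that the site-scale persistence sweep detects, mirroring
measured radial actin profiles (low over the disk, peaking at the
ring). Additive Gaussian read noise has SD 0.05, so spots are 20× the
noise SD. All draws come from one seeded generator; identical specs
render identical scenes.

In 3-D mode every punctum carries an hourglass template I(r, z): two
separable Gaussian core lobes, an axial bridge at the neck (amplitude =
`neck_fraction` × the dimmer lobe), two network slabs that are Gaussian
in z with a cubic-onset radial factor peaking at r = 450 nm (so they
live away from the core), and a weak ventral knob below the lower
network. Default constants encode the reported population-mean
geometry — upper core 270 nm (90 nm axial FWHM, 160 nm half-max
radius), lower core 70 nm (80 nm, 140 nm), networks 260/80 nm, ~20 nm
protrusion — and serve as generator truths for recovery tests, never as
oracles for real data.

Because the template is a *sum* of components, the closed-form lobe
FWHM (2.355 σ) is not exactly the FWHM of the composite core profile.
Morphometry recovery is therefore scored against a continuum oracle: an
independent implementation of the same feature definitions evaluated on
1 nm (profiles) and 5 nm (contour) grids straight from the analytic
template, with hand-rolled peak finding and flood fill. A bridge-free
two-lobe subcase is additionally checked against the closed form. The
test suite requires median peak-z and FWHM errors within one z-step
(10 nm) over 110 randomized templates, and protrusion within one z-step
on noiseless templates.

What the generator does **not** emulate: optical PSFs and their
anisotropy, localisation-event statistics of single-molecule imaging,
depth-dependent background, podosome-to-podosome intensity variation
within a ring, temporal dynamics, and the semi-manual steps of
filament tracing. Passing the synthetic benchmark therefore shows that
the pipeline's geometry, significance logic, and refinement behave as
specified under realistic contrast and noise — not that it reaches any
particular accuracy on a given real dataset.

## Validation and statistics

Detections are matched to ground truth one-to-one, greedily by
ascending pair distance, accepting only pairs within the match radius
(0.4 µm by default — the criterion used when the original pipeline was
compared with manual annotation); an optimal-assignment matcher is
available behind a flag and is tested to give the same number of
matches on well-separated truths. FDR = FP/(TP + FP) (0 when there are
no positives) and recall = TP/(TP + FN). Ring podosomes are the truth
set; planted distractors are not podosomes, so detecting one counts as
a false positive.

Group comparisons use the two-tailed Mann–Whitney U test: exact by
exhaustive enumeration of group assignments (midranks under ties) for
pooled sizes ≤ 18, the tie-corrected normal approximation otherwise.
Quartiles use linear interpolation (stated explicitly because whisker
placement depends on the convention); whiskers extend to the last datum
within 1.5 × IQR of the box. Bonferroni multipliers are supplied by the
caller and cap the adjusted p at 1.

## Problem sizes and runtime

The detection benchmark uses ten 400 × 400-pixel fields (~460–560
planted podosomes pooled); a full benchmark run, including rendering
and both persistence scales per field, takes well under a minute on one
CPU. Persistence is exact (no subsampling); its cost is one union-find
pass per degree, near-linear in pixel count. Morphometry recovery uses
110 templates on the standard 46 × 60 heatmap grid.

## Known limitations

- Hole loci are interior minima, not geometric centres; candidate site
  centres inherit the eccentricity of the darkest pixel in the disk and
  are only corrected by refinement when enough podosomes are assigned.
- Dim or sparse rings (six podosomes with large gaps relative to the
  site smoothing scale) can fall below the k-means significance split,
  costing recall; the false-discovery rate is conservative by design.
- The additive template's measured half-max radii include network
  contributions and exceed the nominal lobe radii by design of the
  definitions; comparisons should use the continuum oracle, as the
  tests do.
- Exact intensity ties are resolved by row-major order; detection
  avoids them via uniqueness noise, but diagrams of tied images, while
  deterministic, depend on that convention.
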