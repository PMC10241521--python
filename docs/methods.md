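# Methods

## Coordinate and unit conventions

Stacks are arrays indexed `(channel, z, y, x)` with voxel spacing given
as a `(z, y, x)` triple in µm; 2D sections drop the z axis. Physical
coordinates follow the voxel-centre convention (voxel `i` sits at
`i × spacing`), and all geometry — distances, angles, areas, volumes —
is computed in physical µm, never in voxel units. 3D points are ordered
`(z, y, x)`; the 2D rosette geometry uses `(x, y)` to match the shapely
polygon convention, and the boundary between the two is documented at
the module surface. The default voxel spacing is (0.3, 0.1, 0.1) µm,
i.e. a 300 nm z-step with 100 nm pixels; the xy pixel size is not fixed
by any acquisition convention and is configurable everywhere.

## Spindle geometry

The spindle angle is α = arctan(h/D) (computed with `atan2`, so a
vertical spindle with D = 0 gives 90° by continuity rather than an
error) and the inter-centrosomal distance is the Euclidean pole
separation, asserted equal to D/cos α to 1e-9 µm whenever α < 90°.
α is reported unsigned in [0°, 90°].

Pole positions come from spot detection: a negated
Laplacian-of-Gaussian response at the expected physical spot scale
(anisotropic voxel sigmas), separable non-maximum suppression, then
sub-voxel refinement by an intensity-weighted centroid over a ±3σ
window of the rim-median-subtracted raw image. Pole-to-pole distance is
therefore centroid-to-centroid; manual edge-to-edge calipering of
pericentrin blobs is a near equivalent for well-separated poles but is
not automatable, so the centroid convention is the package's reference
definition. Spots are paired per-cell when an annotation is available,
otherwise by mutual nearest neighbour within a maximum distance
(default 10 µm); leftover spots are reported, not silently dropped.

## Cleavage-plane angle and division classes

θ is measured in the 2D section plane. The tangent to the lumen is
taken at the boundary vertex nearest the centrosome-pair midpoint, its
direction smoothed over an 11-vertex symmetric window — exact on a
regularly discretised circle (within 0.5° for 360 vertices, from the
vertex quantisation of the touch point) and robust to vertex jitter.
The polygon is oriented counter-clockwise so the outward normal is
well defined.

`arccos(a/b)` is inherently in [0°, 90°] because `a` is an unsigned
distance. The full [0°, 180°) range carries a directed convention: the
centrosome axis is directed from the tangent intersection toward the
farthest centrosome and measured from the outward normal, signed by the
tangent direction. Under this convention arccos(a/b) equals
min(θ, 180° − θ) (asserted to 1e-6° on every call), and θ also equals
the angle between the centrosome axis and the lumen-surface normal.
The synthetic rosette generator plants pairs under the same convention,
which is what makes end-to-end recovery exact.

Classification: symmetric/vertical for 45° ≤ θ ≤ 135°, otherwise
asymmetric/horizontal. The defining intervals are open at 45° and 135°,
leaving the boundaries unassigned; they are assigned to symmetric here
(a measure-zero choice, configurable via `boundary_to_symmetric`).
When the centrosome line is parallel to the tangent, b → ∞ and θ = 90°
by continuity; b is reported as `inf`. Group comparisons use the
Pearson chi-square on raw class counts without continuity correction;
a table with an empty class row is reported as degenerate rather than
forced through the test.

## Co-localization

Object-based: per A-object fraction of voxels whose 3D physical
distance to the nearest B-foreground voxel is ≤ d_max, computed via a
Euclidean distance transform of B's complement with anisotropic
sampling; d_max = 0 reduces to exact voxel overlap (verified against an
exhaustive per-voxel oracle). The per-object call uses a fraction
cutoff of 0.5 by default — the operational criterion behind "percent of
ministacks co-localized" readouts is not standardised, so the cutoff is
an explicit, logged parameter.

Manders: thresholded co-occurrence, with the numerator restricted to
voxels supra-threshold in both channels and the denominator to the
channel's own supra-threshold support. Auto-thresholds default to Otsu
per channel (a two-pass Otsu is available for extremely sparse
channels). Because pointwise thresholds misclassify isolated noisy
voxels — holes inside true signal, speckles outside it — the support
masks are regularised by a face-connected binary opening followed by
closing; whole components the opening would erase (objects thinner than
the structuring element but of ≥ 4 voxels) are restored, so small
genuine objects survive while single-voxel noise does not. On clean
binary phantoms this pipeline is the identity and planted M1 is
recovered exactly; at peak SNR 8 with auto-thresholds recovery is
within ±0.02 across planted M1 ∈ {0, 0.25, 0.5, 0.75, 1} (the tests
assert ±0.03). Costes-style automatic thresholding and pixel
correlation coefficients are out of scope.

## Intensity statistics and morphometry

ROI skewness uses the population convention g1 = m3/m2^{3/2} (the
convention of common image-analysis software); the sample-adjusted
variant is a flag. A constant ROI has undefined skewness and is
signalled as NaN rather than raised, so batch tables can carry the
undefined marker. Compartment enrichment integrates a channel over
disjoint masks (apical process / soma / basal process) and normalises
to fractions. Mitotic indices and phase distributions are pure
arithmetic over annotation tables — phase calls (P, P-M, M, A, T) are
manual input, never inferred from chromatin morphology.

The EdU-style positivity rule ("signal intensity above 50%") does not
define its reference level; the default reads it as 50% of the maximum
per-object mean intensity in the image, with an absolute-cutoff
alternative. This is an explicit interpretation, flagged as such.

TUBB3 density is foreground area (µm²) per total cell; average neurite
length keeps its operational area-based definition — TUBB3⁺ area minus
the part overlapping a dilation of the nuclei mask (default perinuclear
radius 2 µm, a choice: the source procedure names a nuclei mask without
a radius), per TUBB3⁺ cell, in µm²/cell. It is an area proxy, not a
skeleton length.

### Cilium tracing

`cilium_length` sums Euclidean segment lengths of an ordered polyline
(arc length, not chord), or measures the longest geodesic through a
skeleton voxel set (full-connectivity graph with physical edge weights,
double Dijkstra sweep). `trace_cilium` produces the polyline from an
image automatically, emulating manual segment-by-segment tracing from
the first to the last pixel mid-point:

1. the tube is masked at half its plateau intensity; the plateau is
   estimated as the median intensity along a provisional skeleton,
   capped at the image maximum — robust against bright spots where the
   cilium bends. For a Gaussian-blurred line source the axial
   half-plateau crossing coincides with the true endpoint, which is
   what makes sub-voxel tip localisation unbiased;
2. the centreline is built from intensity-weighted centroids of 0.3 µm
   slabs along the mask's geodesic axis and lightly smoothed — a plain
   skeleton path overestimates length by up to ~50% on anisotropic
   grids through staircase zig-zag, which the slab averaging removes;
3. for stubby tubes whose skeleton collapses (< 2 µm) a straight
   principal-axis model is used instead (the arc-vs-chord error of a
   gently curved 2 µm cilium is < 1%);
4. each end is extended to the sub-voxel half-plateau crossing along
   the local tangent, interpolated in the image.

Planted lengths of 2–10 µm at curvatures up to 0.2 rad/µm are recovered
within 5% (typically ~1%).

## Synthetic phantoms

The generators exist to give every measurement a ground truth with the
statistical structure the measurement assumes; they are not
photorealistic microscopy simulators. Shared optics/noise model: point
sources render as anisotropic Gaussians whose width combines the
planted source size with a Gaussian PSF stand-in (σ = (0.35, 0.13,
0.13) µm (z, y, x) — axially elongated like a confocal PSF); noise is
Poisson shot noise at a fixed photon gain (50 photons per unit
amplitude) plus additive Gaussian read noise, with the peak SNR defined
as peak planted amplitude over read-noise σ. `snr=None` is exactly
noise-free. All randomness flows from one `numpy` Generator per call,
so a fixed seed yields byte-identical stacks and manifests.

Continuous ground truth (pole positions, angles, overlap counts,
polylines, areas, class labels) is stored in a JSON-serialisable
manifest; rasterisation error belongs to the image and is never used as
truth.

- **Spindles**: cells on a non-overlapping grid (18 µm boxes), each
  with a chromatin plate and two pole spots at planted ICD and α; per
  cell values can be fixed, listed, or drawn uniformly from ranges.
- **Co-localization**: A objects are uniform boxes; each is planted
  fully inside a dilated B box, far from all B, or (one object at most)
  partially inside using a raster-prefix construction that hits the
  planted inside-voxel count exactly, so planted M1 equals the target
  to within one voxel's intensity share. B boxes containing A are
  dilated beyond the PSF reach so that "fully inside" survives blurring.
- **Rosettes**: a circular lumen ring, nuclei, and centrosome pairs at
  evenly spaced angular slots outside the lumen, each pair axis planted
  at θ from the local tangent under the shared directed convention.
  With `asym_fraction`, exactly `round(fraction × n)` cells receive
  asymmetric angles (uniform in [5°, 40°] ∪ [140°, 175°]) and the rest
  symmetric ones ([50°, 130°]), keeping every planted angle ≥ 5° from
  the class boundaries.
- **Cilia**: a fixed-step path whose direction rotates at
  `tortuosity × 0.5` rad/µm around a slowly drifting axis — a gently
  curved arc, as primary cilia are; the polyline arc length equals the
  requested length exactly. (A jagged random walk would plant
  sub-resolution wiggle that no image-based measurement could recover,
  which would test the phantom, not the method.)
- **Neurite fields**: nuclei as non-overlapping disks; the TUBB3 mask
  grows random-walk strands from the TUBB3⁺ nuclei to an exact
  foreground pixel count, so planted area and density are exact.

What the phantoms do not emulate: optical sectioning physics, spectral
bleed-through, uneven illumination, tissue scattering, touching or
overlapping cells, and real biological shape variability. Passing the
recovery suite therefore demonstrates correctness of the geometry,
statistics and bookkeeping under controlled imaging conditions — not
robustness to every artefact of real organoid imagery, where the
interactive steps the package replaces (threshold choice, ROI drawing,
phase annotation) remain the dominant source of variation.

## Thresholding and segmentation defaults

The original analyses used interactive per-image thresholds, which are
unrecoverable; the package defaults to Otsu and logs every threshold
actually applied. Connected components use full connectivity
(8-connected in 2D, 26-connected in 3D), matching common
particle-analysis behaviour, and labeling is verified against an
exhaustive flood-fill oracle. The particle-size cut is physical: the
15 µm² nuclear cut applies to area in 2D; in 3D the documented analogue
is 15 µm² × z-step in volume.

## Problem sizes used in validation

The test suite and the acceptance script validate at desk scale chosen
to exercise every code path with comfortable statistics: 50-cell
spindle stacks (≈ 1400 × 1300 × 27 voxels) at SNR 8 and noise-free,
100-mitosis rosettes, 200 random ≤ 32³ stacks for the exhaustive
co-localization oracle, 5 planted M1 levels × 10 noisy replicates, and
five cilium lengths spanning 2–10 µm. The full suite runs in about a
minute on one CPU.
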