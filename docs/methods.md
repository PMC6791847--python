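# Methods

## Input model and coordinate conventions

The unit of analysis is one telomere attachment site: a labelled 3D
point model exported from a segmented electron tomogram in the
`model2point` text dialect (five whitespace-separated columns: object
id, contour id, x, y, z in pixels).  A per-site label map assigns each
object to one structure class (lateral element, central element,
attachment plate, inner/outer membrane, LINC filament, microtubule,
other), and a per-site pixel size (nm/pixel) converts coordinates on
load; an optional per-axis triple supports anisotropic tomograms but
the default is isotropic.  Point files are treated as voxel-centre
coordinates with no origin shift — every downstream quantity is a
distance, so only relative positions matter.  One filament is one open
contour of a LINC-filament object; contours with fewer than two points
are rejected at parse time with the offending contour named.  Binary
IMOD models and any image processing are out of scope.

## Per-filament geometry

* **Path length** is polyline arc length (sum of segment norms).  The
  source measurements were read from the segmentation tool; arc length
  is the natural re-implementation and is assumed equivalent.
* **Linear distance** is the Euclidean distance between the first and
  last stored vertex; the **stretch factor** is their ratio, in (0, 1]
  (exactly 0 only for degenerate closed paths, which are reported, not
  rejected).
* **Origin extraction**: the origin is the filament vertex minimising
  the minimum Euclidean distance to the lateral-element point cloud.
  Ties break to the lowest vertex index (ties are measure-zero on real
  data; the rule only pins down determinism).  When the origin is the
  last vertex the filament is re-oriented so the origin leads.  A
  membrane-based variant (nearest vertex to the inner-membrane cloud)
  is available via `origin_reference="inner_membrane"` for sensitivity
  checks, since the anchor can equivalently be described as the
  membrane intersection.
* **Plate assignment**: each site has two attachment plates.  When
  plate points were segmented, origins are assigned to the nearer of
  the two plate centroids (found by 2-means on the plate points, which
  form two well-separated blobs); otherwise 2-means on the origins with
  a fixed seed.  Plate labels are ordered along the axis of largest
  centroid separation so they are stable under jitter.

## Nearest-neighbour distances

Filament-to-filament distance is the *point-set* minimum over all
vertex pairs, matching how segmented point coordinates are compared; a
true segment-to-segment variant (`method="segments"`) exists for
sensitivity analysis and can only be smaller.  "Neighbouring" means the
nearest other filament within the same site — one sample per filament,
which matches one-histogram-entry-per-filament reporting; cross-plate
neighbours are never the minimum in practice.  Singleton sites are
skipped with a warning.

The spacing floor ("global minimum distance") is reported two ways,
since a printed floor may be read off a histogram or fitted: the sample
minimum (the headline value, and the maximum-likelihood location of a
shifted exponential) and the rate 1/(mean − min) of that fit.  A
zero-spread sample leaves the rate undefined and is flagged.

Density curves are Gaussian KDEs with Silverman bandwidth by default
(none is stated for the originals); histogram reports default to 2 nm
bins, the granularity of the printed floors.  Mode counting uses local
maxima above 5% of the global maximum, with endpoint maxima counted so
clipped grids do not hide modes.

## Plane fits

For each plate, a plane is fitted to the filament origins by PCA (SVD
of the centred points): centroid, two in-plane axes in descending
variance order, the normal, min–max projection ranges as extents, and
the RMS out-of-plane residual.  Extents are physical side lengths
(min–max), not variance multiples, because the long extent feeds the
packing arithmetic as a length of membrane.  The long side of the
origin patch along the envelope is `extent1`.  Fewer than three points
or collinear points raise a fit error; axis signs follow a fixed
convention (largest-magnitude component positive) for determinism.
Finite samples of a bounded patch make the min–max extent a slight
underestimate of the patch side (≈ (n−1)/(n+1) of it for uniform
sampling), which is visible in the synthetic recovery (~143 nm for a
150 nm plate).

## Microtubule proximity

Distance to the microtubule is point-to-segment from every filament
vertex to the axis polyline — the axis is continuous, no vertex-only
shortcut — and no tubule radius is subtracted (distances are to the
segmented centre line; a radius offset would shift all values equally).
Sites without a microtubule yield an absent value, never zero.
Close/far classification is strict (`distance < cutoff`); the default
scan grid is 20–300 nm in 2 nm steps, bracketing the 100 nm contrast
and the observed ~158 nm plateau edge.  Each scan row reports group
sizes, group means of linear distance, their difference (close − far)
and a Wilcoxon rank-sum p-value; rows whose groups fall below two
filaments are kept as undefined rather than dropped.  The scan reports
raw p-values without multiplicity correction, one per cutoff, and the
cutoffs are strongly dependent — the scan is descriptive, not a
family of independent tests.

## Statistics

* **Kolmogorov–Smirnov (two-sample)**: D by ECDF supremum.  Exact
  p-value by enumeration when n₁·n₂ ≤ 10⁴ (ties trigger a warning —
  the exact null assumes continuity); the asymptotic mode uses the
  Kolmogorov tail with Stephens' finite-sample correction of the
  effective sample size, the convention used by common commercial
  stats tools, so printed values from either convention can be matched.
  On the observed count groups (n = 6 vs 5) these give D = 4/15,
  p = 0.9654 (exact) and 0.9699 (corrected asymptotic).
* **t test**: pooled-variance two-sided by default (no variant is
  stated for the originals); Welch optional.  Identical constant
  samples return t = 0, p = 1 rather than a zero-variance error.
* **Wilcoxon rank-sum**: exact enumeration when min(n₁, n₂) ≤ 10 and
  the data are tie-free; otherwise the normal approximation with
  midrank tie correction and *no* continuity correction, so identical
  samples give p = 1 exactly.
* Summaries are mean ± sample SD (n − 1); SD is flagged NaN for n = 1.
  All tests are two-sided.

## Force and stoichiometry model

Constants: engaged microtubule length per plate 150 nm (the plane-fit
long extent), two plates per site, 43 nm dynein–dynactin footprint,
5 pN per dynein, 1 or 2 dyneins per dynactin, 40 attachment sites per
nucleus (80 telomeres paired two-by-two; the partially synapsed XY
bivalent's third site is available as a 41-site variant), trimeric
SUN/KASH stoichiometry.  The packing rule is per-plate ceiling —
`2 × ⌈150/43⌉ = 8` complexes — because maximum-density packing counts a
partial footprint as reachable; a floor variant (6) is provided as the
conservative bound.  Forces: 8 × 1 × 5 = 40 pN or 8 × 2 × 5 = 80 pN per
site.  Nucleus totals: 40 × 76 = 3040 filaments (reported alongside a
round-to-nearest-thousand convenience value, 3000) and 3 × 3040 = 9120
SUN (and KASH) monomers.  The area-to-length mapping from origin patch
to microtubule is taken as 1-D length packing, the reading consistent
with the printed count.

## Synthetic generator

The generator emulates segmentation-level structure, not imaging
physics.  Defaults are the study conditions: 11 sites with counts drawn
from the observed per-site table (69, 104, 77, 64, 63, 80, 80, 67, 79,
88, 61; alternatively Normal(76, 12²) rounded, or an explicit list),
5/11 of sites carrying a single microtubule (assigned to the last sites,
matching the observed layout), filament lengths from Normal(91, 18²)
truncated at 3 SD, two 150 × 60 nm plates 250 nm apart, origins placed
by dart-throwing with a 5 nm Poisson-disk floor, and filaments grown
outward (≤ 15° tilt) as rippled polylines with ~4 nm vertex spacing.

Ripples are transverse random walks pinned to zero at both endpoints
(preserving the chord), with amplitude found by bisection so the
realised stretch factor hits its target within 10⁻³; the polyline is
then rescaled about the origin to the exact arc length, which preserves
the stretch factor.  Stretch targets are 0.77 without/far from a
microtubule and 0.80 for filaments whose origin lies within 100 nm of
the axis, with 0.02 SD per-filament jitter; the observed ≈4 nm linear
excess near the microtubule then *emerges* from target × length rather
than being hard-coded.  (The true per-filament stretch values were
published only as density plots; 0.77/0.80 are chosen to reproduce the
printed cohort linear means 0.77 × 91 ≈ 70 nm and 0.80 × 91 ≈ 73 nm,
and are exercise values for the pipeline, not claims about the data.)
A ≥ 2 nm whole-filament clearance is enforced by rejection: each
filament redraws its ripple up to 10 times and, if still blocked, its
origin (respecting the spacing floor) up to 100 times.  Membranes,
plates and synaptonemal-complex elements are emitted as coarse jittered
planar/ribbon scaffolds sufficient for origin extraction and plate
assignment — not anatomical meshes.  The lateral-element ribbon spans
the plate footprint so that each filament's closest vertex to it is its
membrane anchor.

All randomness flows from one named `numpy` generator seeded from the
config; regeneration is byte-identical and the manifest records the
seed and a config hash.  Ground truth (plate label, targets, near-MT
flag, realised values) is emitted per filament.

What passing tests on synthetic data do **not** show: robustness to
segmentation noise, curved membranes, filament density gradients, or
missing-wedge anisotropy — none of which the generator models.  The
exactly-reproducible quantities (count-table summaries, KS on the count
groups, packing/force/stoichiometry arithmetic) are independent of the
generator.

## Problem sizes and runtime choices

The acceptance script regenerates a 50-site cohort (~3800 filaments) —
large enough that length mean/SD, the spacing floors and the
near-microtubule stretch excess are recovered within tight tolerances —
and completes in seconds; the test suite uses 11-site cohorts and
500-draw calibrations.  Whole-filament nearest-neighbour search is an
exact O(n²) pairwise scan per site (n ≈ 100 filaments of ~25 vertices),
which is well within budget without spatial indexing.

## Known limitations

* Origin extraction assumes the lateral-element cloud sits below the
  filament anchors; grossly misaligned or sparse lateral-element
  segmentations could pull origins to interior vertices.
* The point-set distance convention slightly overestimates true
  polyline clearances (by up to ~half a vertex spacing); the segment
  variant bounds the effect.
* The exact KS p-value treats tied counts as continuous data (with a
  warning); with 11 integer counts, conventions differ at the third
  decimal.
* The force model is an upper-bound packing argument, not a mechanical
  model: load sharing among ~76 filaments, LINC elasticity, and the
  dynein duty cycle are outside its scope.
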