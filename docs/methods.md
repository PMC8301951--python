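# Methods

## Problem and marker model

Stereotactic neurosurgery and multi-modal image registration need landmark
points that can be found automatically in MRI. The marker modelled here is a
cylindrical housing holding two spherical cavities of radius r = 3.5 mm
filled with an MR-active substance, mounted on a cranial bone anchor. In
T1/T2-weighted images the spheres appear as bright balls inside a dark
housing. A valid marker is exactly two detected sphere centroids whose
distance lies in a corridor of 11.0 ± 1.0 mm; the vector between the
centroids is the marker's axis, which encodes the anchor direction. Pairing
doubles as a false-positive filter: solitary detections with no in-corridor
partner are discarded.

Because the two spheres are constructively identical, the axis is only
defined up to sign; reported directions use the representative whose
largest-magnitude component is positive.

The pipeline has three stages: (1) load / resample to isotropic voxels /
pre-process; (2) localize sphere candidates with one of four detectors;
(3) pair candidates into markers and report pose (midpoint + unit axis).
The only parameters a user must supply are the sphere radius and the pair
spacing; everything else adapts to the voxel size or has validated
defaults.

## Detectors

**Bidirectional circular Hough transform (hough).** Spheres are circles in
every slice stack. Each slice of two orthogonal stacks is edge-detected
with a first-order derivative of Gaussian (sigma 1 voxel); pixels above the
95th percentile of nonzero gradient magnitudes vote along their gradient
direction ± 0.35 rad, inward and outward, at the voxel radii
{r/s − 1, r/s, r/s + 1} (rounded half away from zero), all into one 2D
accumulator per slice. Votes are deposited by bilinear splatting of the
fractional circle-centre coordinates; integer rasterization was measured to
bias peaks by up to a voxel. Per-slice accumulators are restacked to 3D and
the two stacks multiplied element-wise **without** per-stack normalization:
normalizing each stack by its own peak cancels precisely the advantage a
sphere (strong in both stacks) holds over an elongated object (strong in
one), and in a controlled experiment made a radius-matched cylinder
outscore a sphere. Thresholds are taken relative to the blended maximum
(default 0.3), so the absolute vote scale is irrelevant downstream.

**Spherical-kernel convolution (kernel).** The volume is normalized to
mean 0 / sd 1 and convolved (valid region, cropped borders) with a
two-valued kernel: +1 inside a ball of the marker radius, k_out outside,

    k_out(s_v) = −0.5 − 1 / (1 + e^(−c (1 − s_v))),  c = 3,

a logistic law in the voxel spacing s_v with range (−1.5, −0.5) and
k_out(1 mm) = −1. Coarser grids have fewer outside voxels per kernel, so
each gets a milder penalty. The kernel half-size is floor(r/s) per axis
(7×7×7 at r = 3.5 mm, s = 1 mm; cuboidal for anisotropic spacing) and the
inside ball is intersected with the kernel cube rather than shrunk to fit:
shrinking leaves radial slack that flattens the response peak into a
plateau and measurably degrades localization at fine voxel sizes (median
error 0.65 mm vs 0.26 mm at s = 0.6). The response is min–max rescaled to
[0, 1]; candidates are local maxima above 0.8 of the maximum. That default
separates the flat background plateau of the response (0.43–0.77 across
voxel sizes 0.6–1.6 mm on phantoms — the head drives the minimum of the
min–max scale) from sphere peaks (≥ 0.86).

**Connected-component analysis (cca).** Gaussian blur (sigma 0.5 voxel)
for noise cancellation; unsharp mask (sigma 1.0 mm, amount 1.0) to push the
housing ring below the background threshold — the sigma is fixed in mm, not
voxels, because a 1-voxel unsharp at 0.6 mm is too weak and the spheres
merge with their housing; binarization at the first threshold of a
four-class multi-Otsu (256-bin histogram); 6-connected component labeling;
then filtering by equivalent radius (|r_eq − r| ≤ 0.35 r) and roundness
(≥ 0.6), where roundness is the surface area of the equal-volume sphere
divided by the area of a triangulated iso-surface of the component mask.
Component centroids (intensity-free voxel-centre means) are the candidates,
with sub-voxel accuracy. Note the triangulated surface of a binary mask
overestimates a smooth sphere's area by about 8%, so digitized spheres
score ≈ 0.92 rather than 1.0; the 0.6 cut-off leaves ample margin, and
cubes (analytic roundness 0.806) and rods score clearly lower.

**Determinant-of-Hessian blob detection (blob).** Each slice along one
axis (axis 0 by default — the 2D character of the method is retained
deliberately) is lifted to scale space L(·; t) by Gaussian smoothing with
variance t, and the scale-normalized DoH response t²(Lxx·Lyy − Lxy²) is
computed at the single characteristic scale t = (r/s)²/2 (the standard
r = sigma·√2 relation). All positive local maxima of the stacked response
are candidates — deliberately permissive. In the detection pipeline, maxima
are merged within one sphere diameter, since two true centres can never lie
closer than that. Each candidate gets a descriptor: the six unique
normalized second-order central moments of the (non-negative) intensity in
a cubic window of half-size r. A uniform ball of radius R has moment matrix
(R²/5)·I (trace 3R²/5), which serves as the characteristic signature.
k-means (10 restarts, fixed seed) is run for k = 1..8; the cluster count is
the smallest k whose inertia falls below 5% of the single-cluster inertia,
else the knee (maximum chord distance on the log-inertia curve); a
negligible relative scatter short-circuits to a single cluster. The cluster
whose mean descriptor is nearest the analytic signature — using the full
six-vector, because anisotropic clutter can match the sphere trace while
differing in shape — is kept. Residual false positives are left for the
marker model.

## Synthetic phantom

Real cadaver-head acquisitions are not available, so a generator emulates
them: a 104 mm cube field of view; an axis-aligned ellipsoidal "head"
(semi-axes 26, 22, 20 mm, intensity 0.5); five markers placed on outward
rays from the head centre at the local ellipsoid radius + 12 mm, each a
pair of spheres (intensity 1.0, r = 3.5 mm) exactly 11 mm apart along a
uniformly random axis, each sphere wrapped in a concentric housing shell
(outer radius 5 mm, intensity 0.1); background 0; optional additive
Gaussian noise (default sd 0.02; the end-to-end acceptance study runs
noise-free). Sphere edges are rendered with partial-volume blending
(inside fraction from a 3³ subgrid), matching the smooth edges of real
scans and preventing trivially easy centroid tests. Ground truth records
the exact continuous-space centres. Cross-marker sphere separation is
enforced at ≥ 13 mm so greedy pairing is unambiguous.

What the phantom does *not* emulate: tissue texture and anatomy inside the
head (a constant ellipsoid), T1/T2 contrast physics, Rician noise
statistics, bias fields, and partial housing/skin contact. Detector
rankings on phantoms therefore speak to geometry and contrast handling,
not to anatomical clutter — the published false-positive counts on real
heads are far higher than phantom counts, especially for the slice-wise
methods.

## Evaluation

Detections are matched one-to-one to ground-truth centres greedily by
ascending distance with a 14 mm acceptance threshold (the published
matching criterion; configurable). F1 = tp/(tp + (fp+fn)/2) is computed
before (F1bm) and after (F1am) the marker model. Positioning error Ep is
the Euclidean distance of matched detections; spacing error Es is
|detected spacing − 11 mm| per complete marker. The voxel-quantization
accuracy limit is the norm of a half-voxel offset per axis, (√3/2)s ≈
0.86·s; the worst-case axis-orientation error for positioning error ep
orthogonal to the axis is arctan(2·ep/11) with both endpoints displaced
(single-endpoint variant available).

## Numerical choices and degeneracies

- Local maxima use a Euclidean-ball neighbourhood of radius min_distance
  (mm), realized as an inscribed-box maximum filter plus an exact ball
  check. A Chebyshev box was rejected: at the 2r = 7 mm suppression
  distance a box swallows the weaker twin of an obliquely oriented marker
  even though the pair distance is 11 mm. Plateau ties resolve to the
  lexicographically smallest index; returned maxima are additionally
  thinned so no two are closer than min_distance (descending value).
- All detected positions are voxel centres in physical mm (CCA centroids
  are continuous); no sub-voxel peak interpolation is applied, so the
  0.86·s limit governs the slice-wise and convolution detectors.
- Constant volumes raise a degenerate-input error in normalization;
  histograms with fewer populated bins than classes raise a degenerate
  histogram error; zero-intensity moment windows are flagged and dropped.
- Resampling is linear (map_coordinates, nearest padding), preserving the
  origin and the physical extent to within one voxel.
- Determinism: phantoms are bit-reproducible per seed; k-means uses a
  fixed seed with 10 restarts; greedy pairing is ordered by descending
  score with index tie-breaks.

## Problem sizes

The test suite and the acceptance study use 104 mm phantoms at voxel sizes
0.6–1.0 mm (up to 174³ voxels), five markers each; unit tests use smaller
two-marker phantoms. A full four-detector study over three voxel sizes
completes in well under a minute on one CPU.

## Known limitations

- The blob detector's slice-wise processing biases some maxima along the
  slicing axis by up to about a voxel when the housing shell interacts
  with the single smoothing scale; for unfavourable marker orientations
  one pair can drift outside the ±1 mm corridor and be lost at the pairing
  stage. This mirrors the published behaviour of the method (its
  after-model F1 was below 1.0 at most voxel sizes and its spacing error
  the largest of the four detectors).
- The kernel and Hough detectors quantize centroids to voxel centres, so
  their positioning error grows linearly with voxel size; CCA is the most
  accurate throughout, also as published.
- Moment clustering assumes marker-sized bright blobs are rare relative to
  clutter structure; a field of view dominated by sphere-sized bright
  objects would defeat the cluster-selection heuristic.
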