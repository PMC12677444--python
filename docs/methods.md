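# Methods

`panomatch` synthesizes panoramic-radiograph-like (PR-like) images from
CT volumes of the jaw by curved multiplanar reconstruction (curved MPR)
and matches them against panoramic radiographs (PRs) with binary
keypoint features. This note documents the model, the tunable
parameters, the synthetic phantom the tests rely on, and the numerical
choices made where the design was genuinely open.

## Reconstruction model

**Arch localization.** Axial slices are binarized at 500 HU (bone and
teeth) and ranked by zero-normalized cross-correlation against a
parametric template of a well-aligned lower dental arch: a parabolic
band 60 mm wide, 50 mm deep and 8 mm thick, centered in the frame with
no translation search. The template only has to *rank* slices, so its
exact geometry is uncritical; ties resolve to the caudal-most slice.
The winning slice is opened and closed with an elliptical structuring
element of 2 mm radius (smaller than the inter-tooth spacing, larger
than speckle noise), reduced to its largest connected component, and
skeletonized. The skeleton's 8-connected pixel graph (diagonal steps
weighted sqrt(2)) is pruned to its longest geodesic path found by a
double Dijkstra sweep — exact on trees, which is what jaw skeletons are
in practice — with lexicographic tie-breaks so the result is fully
deterministic.

**The 14-point curve.** Twelve points are placed at equal arc length
along the pruned path, endpoints included (the method's description
leaves endpoint inclusion open; including them is assumed and
documented here). One extra point per side extrapolates the last
segment's direction at the same spacing, extending the curve over the
distal molars, whose bony support ends before the dentition does in an
axial slice. The curve is then shifted 20 mm cranially so the lower
arch sits below the image center, as on a clinical PR.

**Rotation adjustment.** The occlusal plane is estimated from the
volume: voxels above 3000 HU (enamel and restorations) are flattened
along the left-right axis into a sagittal silhouette and a line is
fitted through the foreground pixel centers. The fit is the principal
axis of the (y, z) scatter rather than an ordinary regression of z on
y: the silhouette is a thick two-band shape, and OLS through such a
band is attenuated toward zero by its vertical thickness (about 20-30%
at a 5 degree tilt in our phantoms), whereas the principal axis rotates
rigidly with the head and tracks tan(tilt) without bias. Subtracting
the fitted slope from each curve point's height — anchored at the most
anterior point, with ties broken toward the list midpoint — gives the
pose-independent base configuration `r_base`. Integer rotation steps R
add `R * 0.04` to the applied slope (about 2.3 degrees per step,
configurable); the method never quantifies its step, and 0.04 was
chosen so the swept range R in [-3, +7] spans roughly -7 to +16 degrees
of occlusal tilt, covering realistic PR orientation variation.
Displacements are exactly linear in R and in anteroposterior distance
from the anchor.

**Curved MPR.** A cubic interpolating b-spline through the 14 points is
re-parameterized by arc length (2048-sample table, within 0.5% of true
arc length at jaw scale). The slab extends 70 mm above and 30 mm below
the curve and +/-15 mm along the local horizontal in-plane normal
(depth rays stay horizontal even for rotated curves, matching a
vertical sampling slab), sampled by trilinear interpolation at 0.10 mm
in plane and 0.35 mm in depth; out-of-volume samples take air
(-1000 HU). Axis sample counts are `floor(extent/step) + 1`, which
yields the method's stated 1001 height and 86 depth samples. Soft
tissue is suppressed by *clamping* values below the high-pass threshold
to the threshold before averaging along depth; clamping (rather than
zeroing) preserves the dynamic range above the threshold. The image is
displayed cranial-up with patient-right on image-left.

**Realignment.** For non-standard rotations, one — and only one —
second pass levels the tooth row: the brightest 10% of projection
pixels are regressed against the *anatomical anteroposterior
coordinate* of their arc station, and the fitted slope is compensated
by per-station height offsets before a single slab regeneration. The
regressor matters: on a left-right-symmetric arch, tilts shift image
content as an even function of arc position, so a regression on raw
arc position would be blind to them; against y the slope equals
tan(tilt) for a tilted head and `-R * 0.04` for rotation step R, which
also makes the rotation machinery measurable (the band slope is
strictly monotone in R when realignment is disabled). A degenerate
regression (no anteroposterior spread among bright pixels) skips
realignment with a warning.

**Finalization.** Bilinear resampling from the native 0.10 mm/pixel to
the target resolution (default 0.115 mm/pixel), then linear min-max
rescaling to 8 bits with round-half-up; a constant image maps to zero
by convention.

## Matching model

Query and database images are preprocessed identically: 8-bit
normalization, center crop/zero-pad to a fixed 180 x 100 mm field, edge
enhancement as the per-pixel maximum over eight compass Sobel masks
(0-315 degrees in 45 degree steps; implemented as the absolute maximum
of the four antisymmetric kernels, normalized by the kernel weight sum
and scaled by the 1.8 gain, clipped to 8 bits), then Gaussian smoothing
with sigma = 1 pixel. Features are multi-scale FAST keypoints with
256-bit binary BRIEF descriptors (scikit-image's ORB), deterministic
for fixed input and settings.

Descriptor matching uses squared Euclidean distance (on 0/1 vectors
this coincides with Hamming distance; a Hamming option exists in the
configuration) with a nearest/second-nearest ratio test at 0.8 on the
squared distances — the method states only "a high degree of
similarity", and the ratio test is the standard deterministic
acceptance rule that degrades gracefully with repeated structure. A
single-entry database accepts its nearest neighbor, and an empty
feature set matches nothing. The bidirectional score is

    score = (matches_AB + matches_BA) / (2 * |A|) * 100 %

with |A| the query feature count; an empty query scores 0 by
convention. Identities with several database images take their maximum
image score (the aggregation is not stated by the method; maximum is
assumed). Ranks are 1-based with ties sharing the worst tied rank.
Combined scoring averages the two highest of the four fixed variants
(standard, R+4, R+2, R-2); `R_best` is the per-subject setting with the
most matching points against the subject's own reference. Same- versus
different-identity score distributions are compared with a two-sided
Mann-Whitney U test.

## The synthetic phantom

No clinical data ships with the package; every test input is generated.
A phantom is a voxelized HU scene: parabolic upper and lower dental
arches (the upper 4% wider) of capped-cylinder crowns at 3100 HU
(enamel-like, so the 3000 HU occlusal filter sees exactly the teeth),
equal-arc-length stations with small per-tooth jitter in position
(+/-12% of a tooth spacing), radius and height (+/-8%) and vertical
seat (+/-0.5 mm); bone bands at 900 HU following each arch, the
mandibular band kept clear below the crown bottoms and both bands
truncated to 90% of the arch half-range (in an axial slice the bony
outline ends short of the distal dentition — the reason the method
extrapolates its curve ends); a filled palate plate so maxillary slices
do not mimic the open-band template; a soft-tissue ellipsoid at 50 HU
in an air background; optional very-high-HU restorations in the
occlusal third of chosen crowns; and additive Gaussian noise (default
25 HU). Crown radii are capped at 42% of the distance to the nearest
neighboring crown so the dentition stays a set of distinct connected
components above 1500 HU.

Head tilt rotates the anatomy about the left-right axis through the
arch center. Occlusal overlap is controlled by the inter-arch vertical
gap: +3 mm (none), 0 mm (partial), -1 mm (strong, interpenetrating) —
a qualitative reproduction of the clinical overlap strata.

The ground-truth reference PR is rendered from the *untilted* twin of
the same dentition (a panoramic machine positions the head upright)
along the true arch with the package's own projection rule, then
independently degraded (0.8 px Gaussian blur and 2%-of-range noise) so
reference and PR-like images share structure but not pixels. This
emulates the cross-modality gap in geometry, pose and noise; it does
not emulate true panoramic physics (focal-trough blur, magnification
varying with depth, spine/ghost shadows), real dental anatomy (roots,
pulp, carious lesions), or scanner artifacts. Passing tests therefore
demonstrate the pipeline's internal consistency and its robustness to
pose, overlap, restorations and noise — not clinical identification
rates, which depend on a real PR database.

Cohorts draw arch width 52-68 mm, depth 48-62 mm, 12-16 teeth per arch,
tooth height 8-11 mm, radius 2.6-3.3 mm, head tilt +/-2.5 degrees,
Poisson(1.5) restorations (capped at 4) at 4000-9000 HU — ranges chosen
once to mimic inter-patient variability reported for adult dentition.

## Problem sizes

Routine verification uses reduced sizes chosen so the full suite runs
in minutes on one CPU, with every algorithmic step intact:

* cohort studies: 30 identities, 0.7/0.7/0.8 mm voxels, reconstruction
  sampled at 0.4 mm in plane / 1.0 mm in depth, final resolution
  0.4 mm/pixel, 400 keypoints per image;
* the full 7 x 9 x 12 parameter grid: miniature phantoms (44 x 42 mm
  arches, 1 mm voxels), a 50 x 35(+15) x 24 mm slab, a 60 x 40 mm
  matching crop, 150 keypoints, raised edge gain (coarse voxels spread
  edges over several 0.115 mm pixels);
* the tooth-count projection check samples depth at the native 0.35 mm
  (coarser depth steps alias crowns into stripes).

In the sweep, each curved slab is sampled once per rotation (with the
realignment offsets computed at the default 500 HU high-pass), each
projection once per high-pass value, and only
finalization/preprocessing/feature extraction run per resolution; this
factoring changes no per-setting output except that realignment is not
recomputed per high-pass value.

## Numerical choices and edge cases

* Slice ordering by ImagePositionPatient z, never file name; overlapping
  slice series use the inter-slice distance as spacing.
* HU thresholds are strict (`>`); threshold masks are monotone in the
  cutoff.
* 8-bit rescale: linear min-max, round-half-up, constant image -> 0.
* Sample counts per slab axis: floor(extent/step) + 1 (endpoint kept
  when it lands on the grid).
* Double-sweep geodesic tie-breaks: lexicographically smallest pixel.
* The cubic spline through 14 equal-arc knots deviates from the
  analytic arch by at most ~0.4 mm, concentrated at the tightly curved
  apex; elsewhere the deviation is below 0.05 mm.
* Empty feature sets warn and score zero; degenerate bright-band
  regressions warn and skip realignment; a sweep setting that fails
  reconstruction is recorded as missing, not fatal.

## Known limitations

* The linear-in-y form of the rotation shift is assumed; a
  curve-length-based form would differ for strongly asymmetric arches.
* The occlusal estimator needs voxels above 3000 HU; low-dose or
  heavily artifacted series would require a lower teeth threshold.
* Upper-arch extraction, per-tooth segmentation and metal-artifact
  handling are out of scope; strongly artifacted volumes are the
  caller's responsibility to exclude.
* Identification rates measured on phantom cohorts are properties of
  the synthetic study conditions, not estimates of clinical
  performance.
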