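# Methods

This note documents the models and numerical choices behind each component,
the conditions of the phantom validation studies, and what those studies do
and do not establish about real data.

## Workspace

A workspace is a directory holding one chunked HDF5 file per layer under
kind-named subdirectories (`raw/`, `feature/`, `supervoxels/`, `annotation/`,
`prediction/`, `objects/`), plus a JSON metadata document and a YAML session
file. One file per layer allows independent chunk tuning and safe deletion of
single layers. Axis order is `(z, y, x)` — slice, row, column — 0-based, and
regions of interest are half-open boxes. Chunk shape defaults to
`(32, 128, 128)` (a full-slab read touches few chunks while z-slicing stays
cheap) and is set globally at creation; chunking never affects values, only
I/O granularity.

Raw volumes are min–max rescaled to `[0, 1]` on import, with constant
volumes mapping to 0. This is a deliberate convention of this package: it
pins the scale of every threshold and sigma parameter across datasets, at
the cost of discarding the original intensity units (which object
measurements then inherit). Integer layers (supervoxels, annotations,
predictions, objects) round-trip bit-exactly; float layers are stored as
float32.

Every pipeline stage records its operation name and parameters into the
session, which serializes to a single human-readable YAML document. Replaying
a session on a fresh workspace of the same shape reproduces the layer
structure; stochastic stages are fixed by the config's single global seed.

## Filter bank

Filters are registered by name with typed parameter schemas so configs can
be validated before execution. Definitions follow the standard forms
(`simple_invert = max − v`, `gaussian_centre = v − G_sigma(v)`,
`gaussian_norm = (v − G_sigma(v)) / sqrt(max(G_sigma(v²) − G_sigma(v)², 1e-6))`,
6-neighbor Laplacian, central-difference gradient magnitude, …). Numerical
choices:

* All convolutions use reflect padding; voxel spacing is assumed isotropic.
* Hessian and structure-tensor smoothing sigma defaults to 1 voxel;
  eigenvalues are sorted ascending by signed value and exposed one channel
  at a time. The mean is subtracted before differentiation so constant
  volumes give exactly zero curvature.
* The structure-tensor *determinant* parameterization is this package's
  convention (determinant of the sigma-smoothed gradient outer-product
  tensor).
* Total variation is Chambolle-style isotropic TV with a weight parameter,
  tolerance 1e-4 and a 200-iteration cap.
* Frangi vesselness uses scikit-image's multi-scale implementation with
  bright ridges, sigmas linearly spaced over `[sigma_min, sigma_max]`.
* Morphology binarizes at a threshold parameter (default 0.5) and uses a
  ball structuring element.
* Wavelet denoising and skeletonization are registry extensions beyond the
  core set; adding further filters is a registration, not an API change.

## Supervoxels

A SLIC-family clustering, implemented directly so that seeding, the distance
form, the search window and fragment handling are exactly as documented:
seeds at the centers of a regular grid of `target_shape` blocks, then
`n_iter` (default 10) rounds of nearest-centroid assignment under

    d² = (Δi / m)² + (Δz² + Δy² + Δx²) / S²,

with `S` the mean seed spacing and a search window of `±target_shape` around
each centroid (the standard `2S` window), followed by centroid updates.
Intensity differences are measured on an 8-bit (0–255) scale; with volumes
normalized to `[0, 1]` this keeps the customary compactness range of the
SLIC literature meaningful, and the default `m = 30` balances a full-range
edge (Δi ≈ 150) strongly against the spatial term while leaving
noise-level differences (a few units) subordinate to it. On a constant
volume the spatial term alone decides assignment and the partition is
exactly the seed grid — the basis of the grid-exactness oracle.

After the final iteration every label is reduced to one 26-connected
component: each non-largest fragment merges into the 26-adjacent neighbor
with the largest current volume (ties to the smallest label id). Because a
merge can extend a label beyond the bounding box captured at the start of a
pass, passes repeat with fresh bounding boxes until no label is fragmented;
the global fragment count decreases monotonically, so this terminates.
Labels are then re-packed to `[0, K)`. The algorithm is deterministic:
identical input and parameters give identical labelings.

Supervoxels are computed on a single user-chosen feature layer. In all
studies here that layer is a TV-denoised volume (weight 0.2): denoising that
preserves edges is what makes the clusters hug object boundaries, whereas a
sigma-2 Gaussian blur smears the step over several voxels and measurably
degrades boundary recall.

## Annotation

Labels are positive integers in a table with optional parent links forming a
forest; 0 is reserved for "unlabeled" and colors are display metadata only.
Painting operates on whole supervoxels and always overwrites (label 0
erases) — overwrite, rather than merge, keeps repeated painting idempotent.
Hierarchy consistency is enforced lazily by `restrict_to_parent`, which
clears child voxels outside the parent mask; enforcing it on every paint
would make interactive-style workflows order-sensitive.

## Shallow segmentation

The per-supervoxel descriptor is the mean and standard deviation of each
feature layer over the supervoxel — the minimal aggregation that captures
both level and texture; the feature matrix is `K × 2·(number of layers)`.
A supervoxel is a training sample iff it contains at least one annotated
voxel, with the majority nonzero label as its class (ties to the smallest
id). Classifiers are scikit-learn estimators behind one interface: random
forest and extra-trees (100 trees, unlimited depth, class-balanced weights),
gradient boosting, and an RBF SVM on standardized features with probability
scores. All are seeded; the full pipeline is a pure function of (features,
partition, annotation, seed).

## Multi-axis 2D prediction and fusion

`slice_stacks` produces the three orthogonal stacks (restacking is an exact
inverse); training pairs align image and mask slices per axis and index.
Augmentations: horizontal/vertical flips (geometric, applied to both),
gamma-style contrast jitter (image only), and elastic distortion from a 4×4
control-point grid of Gaussian displacements (sigma 2 px) upsampled
bilinearly, warping the image with linear and the mask with nearest-neighbor
interpolation. All are deterministic per seed.

Fusion uses hard votes: for every axis and every in-plane rotation (identity
plus any of 90°/180°/270°), each slice is predicted, rotated back, and its
per-pixel argmax cast as one vote, so each voxel receives
`3 × (1 + |rotations|)` votes. The fused label is the per-voxel majority;
ties break by the highest accumulated score and then the smallest class id —
a total, deterministic rule (soft scores are accumulated alongside the hard
votes purely for this tie-break). Non-cubic volumes are supported: slices
within a stack share a shape but differ across stacks, so the predictor
contract accepts arbitrary 2D shapes.

The 2D predictor is a contract (`n_classes`, `predict(image) -> (C, h, w)`),
deliberately decoupled from training so externally trained networks (2D or,
via the same fusion logic applied per slice, 3D models) can plug in. The
trainable predictor shipped here is a pixel classifier: a multi-scale 2D
filter bank (raw, Gaussians at sigma 1/2/4, gradient magnitude, Laplacian of
Gaussian) feeding a seeded random forest, trained on up to 2000 pixels
sampled per training slice. This keeps the full deep pipeline CPU-friendly
and deterministic while exercising exactly the same slicing, augmentation
and fusion machinery a neural predictor would.

## Label splitter

Connected components of the nonzero foreground use 26-connectivity by
default (6 available) in deterministic scan order. Per-object measurements:
mean, standard deviation and variance of intensity ("variation of
intensity" is exported as the variance, sd²; the coefficient of variation
was the other candidate, and both sd and variance columns are present so
either is recoverable); voxel volume; plain-mean centroid; axis-aligned
bounding-box extents and volume; and an oriented bounding box whose axes
are the eigenvectors of the voxel-coordinate covariance, with extents
`max − min + 1` of the projected coordinates (voxel-as-cell convention, so
a single voxel has unit extents), sorted descending. Log volumes use the
natural log. PCA axes are not the exact minimum-volume box; tests bound the
PCA box against an exhaustive rotation search within 5%. Objects touching
the volume border are measured as-is; an optional border-exclusion flag
exists because clipped objects bias size statistics.

Rules apply sequentially: every object starts at the default class and each
rule reassigns all objects satisfying `feature <comparator> threshold`, so
later rules win. The splitter composes — re-splitting one class's objects
never alters objects outside it — enabling nested hierarchies.

## Points, rasterization and ACWE

Point CSVs require a header with `z,y,x` columns (optional `class`, extra
columns ignored). A voxel belongs to a point's ellipsoid iff
`Σ ((v − p)·axis_i / r_i)² ≤ 1`, with axes from an intrinsic z-y-x Euler
rotation; ellipsoids clip at volume borders and overlaps resolve to the
later point in row order (a total, order-deterministic rule).

ACWE refinement is a morphological, level-set-free Chan–Vese scheme on the
voxel grid: each iteration recomputes the two region means, reassigns every
voxel to the nearer mean (weighted by lambda1/lambda2, both default 1), and
applies `smoothing` rounds (default 1) of a 3×3×3 binary median as a
curvature-flow approximation; evolution stops at a fixed point or when a
region would vanish, and `iters=0` returns the input. Because curvature is
handled by smoothing rather than an explicit length penalty, the quantity
the iteration monotonically decreases on noise-free inputs is the two-phase
piecewise-constant *data* energy; `chan_vese_energy` therefore defaults to
`mu = 0` and takes `mu > 0` only for scoring.

## Phantoms and validation studies

The phantom generator places non-overlapping bright objects — spheres or
straight cylinders at random orientations (curvature is out of scope for
fixtures) — with at least a two-voxel gap, on a constant background, with
additive Gaussian noise; ground truth labels each object 1..n and centroids
are returned as a point set. Scribbles sample a per-class fraction of voxels
(background mapped to its own label), guaranteeing every class at least one
voxel.

Fixed study conditions (see `volseg.benchmarks`): 64³ volumes with five
blobs of radius 4–8, foreground 0.8, background 0.2, noise sigma 0.05 (0.1
for the deep-vs-shallow study); supervoxels with the 10³ target on the
TV-denoised volume; annotation limited to 5 foreground + 5 background
supervoxels (≈4.6% of ~216); features = sigma-2 Gaussian blur + raw;
random forest, all seeded. These sizes keep every study within seconds on a
single CPU while leaving each pipeline's failure modes (boundary leakage,
class imbalance, vote disagreement) observable.

What passing does and does not show: phantoms have piecewise-constant
intensity, additive white noise, convex or tubular shapes and exact labels.
Real tomograms add texture, shading, artefacts, ambiguous boundaries and
annotation error, so the studies validate the *mechanics* (contracts,
determinism, conservation laws, exact oracles) and the pipelines' behavior
under controlled noise — not expected accuracy on real data.

## Known limitations

* Voxel spacing is assumed isotropic; sigma/radius parameters are in voxels.
* No GPU path; the trainable 2D predictor is a pixel classifier, not a
  convolutional network (the predictor contract is the extension point).
* Supervoxels use a single feature channel.
* Workspaces are single-process; no remote access or locking.
* The minimum-volume oriented bounding box is approximated by PCA axes.
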