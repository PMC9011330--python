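# volseg

Headless, scriptable segmentation engine for large 3D bioimages (volume
electron microscopy, cryo soft X-ray tomography, X-ray micro-CT and similar
modalities). It targets the common situation where dense manual annotation of
a volume is infeasible: a scientist paints a handful of supervoxels, a
classical classifier propagates those labels through the whole region of
interest, and that cheap segmentation in turn supervises a 2D model that is
fused across all three slicing directions to segment the full volume. All
artifacts live in an on-disk workspace of chunked HDF5 layers, and every
pipeline can be validated end to end on generated phantom volumes with exact
ground truth — no external data, GUI or GPU required.

## What it computes

**Supervoxels.** A SLIC-family clustering partitions the volume into compact
regions of roughly `t³` voxels (default `10×10×10`) that respect image
boundaries. Voxels are iteratively assigned to the nearest of K grid-seeded
centroids under the joint distance

```
d² = (Δi / m)² + (Δz² + Δy² + Δx²) / S²
```

with compactness `m` (default 30, intensity differences on a 0–255 scale),
mean seed spacing `S`, and a `2t` search window; disconnected fragments are
merged into their largest 26-adjacent neighbor.

**Shallow pipeline.** Each supervoxel is described by the mean and standard
deviation of each feature volume (a registry of ~20 filters: Gaussian,
total-variation and median denoising, Hessian eigenvalues, Frangi
vesselness, morphology, local Gaussian statistics, …). Supervoxels touched
by annotation become training samples (majority label) for a random forest /
extra-trees / gradient-boosting / SVM classifier, which then labels every
supervoxel; labels project back to voxels.

**Multi-axis deep pipeline.** The volume is sliced into axial, coronal and
sagittal stacks (a 256³ volume yields 768 2D images); a pluggable 2D
predictor scores every slice, optionally after 90°/180°/270° in-plane
rotations, and each prediction casts one hard vote per voxel. The fused
label is the per-voxel majority, ties broken by accumulated score then
smallest class id. A trainable filter-bank + random-forest pixel classifier
is included; any object with `n_classes` and `predict(image) -> (C, h, w)`
can stand in, e.g. an externally trained U-Net.

**Label splitter.** Connected components of a segmentation are measured
(intensity statistics, volume, axis-aligned and PCA-oriented bounding boxes,
centroid) and split into classes by an ordered list of threshold rules,
later rules overriding earlier ones.

**Geometric points.** CSV point annotations rasterize into ellipsoidal
masks, optionally refined by Active Contours Without Edges (Chan–Vese
region competition), and can seed the shallow pipeline — the distributed
annotation path.

## Worked example

```python
import numpy as np
from volseg import filters, shallow, supervoxels, synthetic

spec = synthetic.PhantomSpec(shape=(64, 64, 64), n_objects=5,
                             fg_intensity=0.8, bg_intensity=0.2,
                             noise_sigma=0.05, seed=7)
volume, truth, centroids = synthetic.generate_phantom(spec)

den = filters.apply_filter(volume, filters.FilterSpec("total_variation", {"weight": 0.2}))
part = supervoxels.compute_supervoxels(np.clip(den, 0, 1),
                                       supervoxels.SupervoxelParams((10, 10, 10)))
print(supervoxels.summarize_partition(part))

ann = synthetic.scribble_from_truth((truth > 0).astype(np.int32), 0.02, seed=1)
blur = filters.apply_filter(volume, filters.FilterSpec("gaussian_blur", {"sigma": 2.0}))
pred = shallow.segment({"blur": blur, "raw": volume}, part, ann, seed=3)
fg = pred == 1
print("Dice:", 2 * (fg & (truth > 0)).sum() / (fg.sum() + (truth > 0).sum()))
```

prints

```
{'count': 216, 'mean_volume': 1213.6296296296296, 'min_volume': 522, 'max_volume': 1560}
Dice: 0.9998313374936751
```

i.e. 216 supervoxels averaging ~1214 voxels against the 1000-voxel target,
and a voxel Dice of 0.9998 against the phantom's ground truth from scribbles
covering 2% of the voxels.

The same flow is available from the shell:

```
vol phantom --shape 64,64,64 --n 5 --seed 7 --out wsdir
vol filter wsdir --name total_variation --param weight=0.2 --out tv
vol supervoxels wsdir --in tv --shape 10,10,10 --out sv1
vol shallow train-predict wsdir --ann ann1 --sv sv1 --features tv,raw --seed 3 --out pred1
```

or declaratively via `vol run wsdir --config pipeline.yaml`, which also
records every stage into the workspace session for replay on a new volume.

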