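"""End-to-end validation studies on phantom volumes.

Every study builds its own inputs from the phantom generator, runs one of the
package's pipelines, and scores the result against the phantom's exact ground
truth. They are the package's standard self-checks: the acceptance script and
the test suite both call them, so the numbers they produce are always
recomputed from scratch.

Study conditions (fixed):

* Shallow recovery — 64^3 two-class blob phantom, foreground 0.8, background
  0.2, Gaussian noise sigma 0.05; supervoxels with a 10^3 voxel target on a
  TV-denoised volume; annotation covers at most 5% of supervoxels; features
  are a sigma-2 Gaussian blur and the raw volume; random-forest classifier.
* Distributed annotation — same phantom family; the only foreground
  supervision is the set of ground-truth centroids rasterized as radius-3
  spheres, with sparse background scribbles sampled far from every point.
* Deep pipeline — noisier (sigma 0.1) phantom; the shallow prediction on a
  half-volume ROI becomes the training labels for the 2D pixel predictor,
  which is then vote-fused over the full volume and compared with running the
  shallow pipeline on the full volume.
* Toy 2D predictor — 32x32 bright-disk images (contrast 0.6, noise 0.1),
  20 training and 5 held-out slices.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from . import filters, multiaxis, shallow, supervoxels
from .annotation import AnnotationVolume, LabelTable, define_label, paint_supervoxels
from .points import EllipsoidSpec, rasterize_points
from .synthetic import PhantomSpec, generate_phantom


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    denom = pred.sum() + truth.sum()
    return float(2 * (pred & truth).sum() / denom) if denom else 1.0


def _standard_phantom(seed: int, noise_sigma: float = 0.05):
    spec = PhantomSpec(
        shape=(64, 64, 64), n_objects=5, fg_intensity=0.8, bg_intensity=0.2,
        noise_sigma=noise_sigma, seed=seed,
    )
    return generate_phantom(spec)


def _denoised_partition(volume: np.ndarray) -> supervoxels.SupervoxelPartition:
    den = filters.apply_filter(volume, filters.FilterSpec("total_variation", {"weight": 0.2}))
    return supervoxels.compute_supervoxels(
        np.clip(den, 0, 1), supervoxels.SupervoxelParams((10, 10, 10))
    )


def _sparse_supervoxel_annotation(part, truth, seed, n_per_class=5):
    """Paint n foreground and n background supervoxels with their true class."""
    rng = np.random.default_rng(seed)
    flat = part.labels.ravel()
    fg_frac = np.bincount(flat, weights=(truth > 0).ravel().astype(float), minlength=part.count)
    fg_frac = fg_frac / np.bincount(flat, minlength=part.count)
    table = LabelTable()
    fg_id = define_label(table, "object")
    bg_id = define_label(table, "background")
    ann = AnnotationVolume.empty(part.shape, table)
    fg_pool = np.flatnonzero(fg_frac > 0.9)
    bg_pool = np.flatnonzero(fg_frac < 0.1)
    paint_supervoxels(ann, part, rng.choice(fg_pool, min(n_per_class, len(fg_pool)), replace=False), fg_id)
    paint_supervoxels(ann, part, rng.choice(bg_pool, n_per_class, replace=False), bg_id)
    return ann, fg_id


def shallow_recovery(seed: int = 7) -> dict:
    """Shallow pipeline recovery on the standard phantom; reports voxel Dice."""
    volume, truth, _ = _standard_phantom(seed)
    part = _denoised_partition(volume)
    ann, fg_id = _sparse_supervoxel_annotation(part, truth, seed)
    blur = filters.apply_filter(volume, filters.FilterSpec("gaussian_blur", {"sigma": 2.0}))
    pred = shallow.segment({"blur": blur, "raw": volume}, part, ann, seed=seed)
    annotated_svs = len(np.unique(part.labels[ann.labels > 0]))
    return {
        "dice": dice(pred == fg_id, truth > 0),
        "n_voxels": int(truth.size),
        "annotated_sv_fraction": annotated_svs / part.count,
    }


def distributed_annotation_recovery(seed: int = 7) -> dict:
    """Points -> rasterize -> shallow segmentation, scored by voxel Dice."""
    volume, truth, centroids = _standard_phantom(seed)
    raster = rasterize_points(centroids, EllipsoidSpec((3, 3, 3)), truth.shape)
    # background scribbles: sparse samples far from every rasterized blob
    far = ndi.distance_transform_edt(raster == 0) > 10
    rng = np.random.default_rng(seed)
    bg_idx = np.flatnonzero(far.ravel())
    bg_pick = rng.choice(bg_idx, size=max(1, bg_idx.size // 200), replace=False)
    table = LabelTable()
    fg_id = define_label(table, "object")
    bg_id = define_label(table, "background")
    ann_labels = np.where(raster > 0, fg_id, 0).astype(np.int32)
    ann_labels.ravel()[bg_pick] = bg_id
    ann = AnnotationVolume(labels=ann_labels, table=table)
    part = _denoised_partition(volume)
    blur = filters.apply_filter(volume, filters.FilterSpec("gaussian_blur", {"sigma": 2.0}))
    pred = shallow.segment({"blur": blur, "raw": volume}, part, ann, seed=seed)
    return {"dice": dice(pred == fg_id, truth > 0), "n_voxels": int(truth.size)}


def fusion_oracle_exact(seed: int = 3) -> dict:
    """Ground-truth-oracle fusion on cubic and non-cubic noise-free phantoms.

    The threshold predictor is exact per slice on a noise-free two-intensity
    phantom, so the fused volume must equal the truth voxel-for-voxel.
    """
    agreements = []
    n_total = 0
    for shape in ((24, 24, 24), (20, 24, 28)):
        spec = PhantomSpec(shape=shape, n_objects=2, noise_sigma=0.0, seed=seed,
                           radius_range=(3, 5))
        volume, truth, _ = generate_phantom(spec)
        for rotations in ((), (90, 180, 270)):
            fused = multiaxis.predict_fuse(
                multiaxis.ThresholdPredictor2D(0.5), volume, rotations=rotations
            )
            agreements.append(float(np.mean(fused == (truth > 0))))
            n_total += truth.size
    return {"agreement": float(np.min(agreements)), "n_voxels": n_total}


def toy_disk_pair(seed: int, size: int = 32):
    """One 2D bright-disk toy image with its mask."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[:size, :size]
    cy, cx = rng.uniform(8, size - 8, 2)
    rad = rng.uniform(4, 8)
    mask = ((yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2).astype(np.int32)
    img = np.where(mask, 0.8, 0.2) + rng.normal(0, 0.1, (size, size))
    return img, mask


def toy_deep_accuracy(seed: int = 0, n_train: int = 20, n_test: int = 5) -> dict:
    """Held-out pixel accuracy of the trainable 2D predictor on disk toys."""
    train = [toy_disk_pair(seed * 1000 + i) for i in range(n_train)]
    test = [toy_disk_pair(seed * 1000 + 500 + i) for i in range(n_test)]
    predictor = multiaxis.train_predictor_2d(train, seed=seed)
    accs = [
        float((np.argmax(predictor.predict(img), axis=0) == mask).mean()) for img, mask in test
    ]
    return {"accuracy": float(np.mean(accs)), "n_pixels": sum(m.size for _, m in test)}


def deep_vs_shallow(seed: int = 7) -> dict:
    """Full deep pipeline versus shallow-only on a noisier phantom.

    The shallow prediction on a half-volume ROI trains the 2D predictor,
    which is fused (with 90-degree rotation augmentation) over the full
    phantom; both pipelines are scored by Dice against the ground truth.
    """
    volume, truth, _ = _standard_phantom(seed, noise_sigma=0.1)
    blur = filters.apply_filter(volume, filters.FilterSpec("gaussian_blur", {"sigma": 2.0}))

    # shallow-only on the full volume
    part = _denoised_partition(volume)
    ann, fg_id = _sparse_supervoxel_annotation(part, truth, seed)
    pred_shallow = shallow.segment({"blur": blur, "raw": volume}, part, ann, seed=seed)
    dice_shallow = dice(pred_shallow == fg_id, truth > 0)

    # shallow on the ROI -> weak labels -> 2D predictor -> fuse full volume
    roi = (slice(0, 32), slice(0, 64), slice(0, 64))
    sub_vol, sub_truth = volume[roi], truth[roi]
    sub_part = _denoised_partition(sub_vol)
    sub_ann, sub_fg = _sparse_supervoxel_annotation(sub_part, sub_truth, seed)
    sub_blur = blur[roi]
    sub_pred = shallow.segment({"blur": sub_blur, "raw": sub_vol}, sub_part, sub_ann, seed=seed)
    pairs = multiaxis.make_training_pairs(sub_vol, (sub_pred == sub_fg).astype(np.int32))
    predictor = multiaxis.train_predictor_2d(pairs, seed=seed)
    fused = multiaxis.predict_fuse(predictor, volume, rotations=(90,))
    return {
        "dice_shallow": dice_shallow,
        "dice_deep": dice(fused == 1, truth > 0),
        "n_voxels": int(truth.size),
    }
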