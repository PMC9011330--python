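"""Multi-axis 2D prediction with per-voxel vote fusion.

The deep pipeline treats a 3D segmentation problem as many 2D ones: the
volume is sliced into three orthogonal stacks (axial / coronal / sagittal),
every slice is predicted by a 2D model — optionally after in-plane rotation
augmentation — and each prediction casts one hard vote per voxel. The fused
label is the per-voxel majority; ties break toward the highest accumulated
class score and then the smallest class id, so fusion is total and
deterministic. With rotation set R each voxel receives ``3 * (1 + |R|)``
votes.

The 2D model is a pluggable contract (:class:`Predictor2D`): anything with an
``n_classes`` attribute and a ``predict(image) -> (n_classes, h, w)`` score
stack works, including externally trained networks. Two concrete predictors
ship here: a threshold baseline and a trainable pixel classifier built from a
multi-scale 2D filter bank and a random forest, which serves as the package's
CPU-friendly trainable 2D model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .errors import ValidationError

AUGMENT_OPS = ("flip_h", "flip_v", "contrast", "elastic")
VALID_ROTATIONS = (90, 180, 270)


@dataclass(frozen=True)
class SlicePlan:
    """Slice counts per axis for one volume; total = n_z + n_y + n_x."""

    shape: tuple[int, int, int]

    @property
    def counts(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.shape)

    @property
    def total(self) -> int:
        return int(sum(self.shape))


@runtime_checkable
class Predictor2D(Protocol):
    """Contract for a 2D per-pixel classifier used by :func:`predict_fuse`."""

    n_classes: int

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Return a per-pixel class-score stack of shape (n_classes, h, w)."""
        ...


def _slice_index(axis: int, i: int):
    idx = [slice(None)] * 3
    idx[axis] = i
    return tuple(idx)


def slice_stacks(volume: np.ndarray) -> tuple[list[list[np.ndarray]], SlicePlan]:
    """Slice a volume into its three orthogonal stacks of 2D images.

    Stack ``a`` contains every plane orthogonal to axis ``a`` in index order;
    :func:`restack` inverts the operation exactly.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {volume.shape}")
    stacks = [
        [volume[_slice_index(axis, i)] for i in range(volume.shape[axis])] for axis in range(3)
    ]
    return stacks, SlicePlan(shape=tuple(volume.shape))


def restack(stack: list[np.ndarray], axis: int) -> np.ndarray:
    """Reassemble one stack of 2D slices along its axis."""
    return np.stack(stack, axis=axis)


def make_training_pairs(
    volume: np.ndarray, label_volume: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Aligned (image, mask) 2D pairs from all three orthogonal stacks."""
    volume = np.asarray(volume)
    label_volume = np.asarray(label_volume)
    if volume.shape != label_volume.shape:
        raise ValidationError(
            f"volume shape {volume.shape} != label volume shape {label_volume.shape}"
        )
    img_stacks, plan = slice_stacks(volume)
    lab_stacks, _ = slice_stacks(label_volume)
    pairs = []
    for axis in range(3):
        pairs += list(zip(img_stacks[axis], lab_stacks[axis]))
    assert len(pairs) == plan.total
    return pairs


def augment_pair(
    pair: tuple[np.ndarray, np.ndarray], ops, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Apply augmentation ops in order; geometric ops hit image and mask
    identically, intensity ops (contrast) hit the image only. Deterministic
    per seed."""
    image, mask = (np.asarray(a) for a in pair)
    unknown = set(ops) - set(AUGMENT_OPS)
    if unknown:
        raise ValidationError(f"unknown augmentation op(s) {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    image = image.astype(np.float64, copy=True)
    mask = mask.copy()
    for op in ops:
        if op == "flip_h":
            image, mask = image[:, ::-1], mask[:, ::-1]
        elif op == "flip_v":
            image, mask = image[::-1, :], mask[::-1, :]
        elif op == "contrast":
            gamma = rng.uniform(0.7, 1.4)
            image = np.clip(image, 0.0, None) ** gamma
        elif op == "elastic":
            image, mask = _elastic(image, mask, rng)
    return image, mask


def _elastic(image, mask, rng, grid: int = 4, sigma: float = 2.0):
    """Elastic distortion: a coarse control-point grid of Gaussian displacements
    (sigma px), bilinearly upsampled; image warped order-1, mask order-0."""
    h, w = image.shape
    disp = rng.normal(0.0, sigma, size=(2, grid, grid))
    zoom = (h / grid, w / grid)
    dy = ndi.zoom(disp[0], zoom, order=1)[:h, :w]
    dx = ndi.zoom(disp[1], zoom, order=1)[:h, :w]
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.array([yy + dy, xx + dx])
    wimage = ndi.map_coordinates(image, coords, order=1, mode="reflect")
    wmask = ndi.map_coordinates(mask, coords, order=0, mode="reflect")
    return wimage, wmask


# ------------------------------------------------------------- fusion ------


def votes_per_voxel(rotations) -> int:
    return 3 * (1 + len(tuple(rotations)))


def select_winners(votes: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pick the winning class per voxel from vote counts and accumulated scores.

    ``votes``/``scores`` have shape (n_classes, ...). Majority wins; ties go
    to the highest accumulated score, remaining ties to the smallest class id.
    """
    n_classes = votes.shape[0]
    winner = np.zeros(votes.shape[1:], dtype=np.int32)
    best_v = votes[0].astype(np.int64).copy()
    best_s = scores[0].astype(np.float64).copy()
    for c in range(1, n_classes):
        better = (votes[c] > best_v) | ((votes[c] == best_v) & (scores[c] > best_s))
        winner[better] = c
        best_v = np.where(better, votes[c], best_v)
        best_s = np.where(better, scores[c], best_s)
    return winner


def predict_fuse(
    predictor: Predictor2D,
    volume: np.ndarray,
    rotations=(),
    return_tally: bool = False,
):
    """Predict every slice of every axis (with optional in-plane rotations)
    and fuse the hard per-pixel votes into a 3D label volume."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {volume.shape}")
    rotations = tuple(int(r) for r in rotations)
    bad = set(rotations) - set(VALID_ROTATIONS)
    if bad:
        raise ValidationError(f"rotations must be within {VALID_ROTATIONS}, got {sorted(bad)}")
    n_classes = int(predictor.n_classes)
    votes = np.zeros((n_classes,) + volume.shape, dtype=np.int16)
    scores = np.zeros((n_classes,) + volume.shape, dtype=np.float64)
    rot_quarters = [0] + [r // 90 for r in rotations]
    for axis in range(3):
        for i in range(volume.shape[axis]):
            sl = volume[_slice_index(axis, i)]
            pos = (slice(None),) + _slice_index(axis, i)
            for k in rot_quarters:
                img = np.rot90(sl, k)
                s = np.asarray(predictor.predict(img), dtype=np.float64)
                if s.shape != (n_classes,) + img.shape:
                    raise ValidationError(
                        f"predictor returned shape {s.shape}, expected {(n_classes,) + img.shape}"
                    )
                if not np.all(np.isfinite(s)):
                    raise ValidationError("predictor returned non-finite scores")
                s = np.rot90(s, -k, axes=(1, 2))
                vote = np.argmax(s, axis=0)
                scores[pos] += s
                v = votes[pos]
                for c in range(n_classes):
                    v[c][vote == c] += 1
                votes[pos] = v
    fused = select_winners(votes, scores)
    if return_tally:
        return fused, votes, scores
    return fused


# ---------------------------------------------------------- predictors -----


class ThresholdPredictor2D:
    """Two-class baseline: foreground iff pixel intensity >= threshold.

    Rotation-equivariant and deterministic, which also makes it the natural
    oracle for fusion round trips on noise-free phantoms.
    """

    def __init__(self, threshold: float = 0.5):
        self.threshold = float(threshold)
        self.n_classes = 2

    def predict(self, image: np.ndarray) -> np.ndarray:
        fg = (np.asarray(image) >= self.threshold).astype(np.float64)
        return np.stack([1.0 - fg, fg], axis=0)


def _pixel_features(image: np.ndarray) -> np.ndarray:
    """Multi-scale 2D filter bank: raw, Gaussians, gradient magnitude, LoG."""
    image = np.asarray(image, dtype=np.float64)
    feats = [image]
    for s in (1.0, 2.0, 4.0):
        feats.append(ndi.gaussian_filter(image, s, mode="reflect"))
    gy, gx = np.gradient(image)
    feats.append(np.hypot(gy, gx))
    feats.append(ndi.gaussian_laplace(image, 2.0, mode="reflect"))
    return np.stack(feats, axis=0)


class FilterBankPredictor2D:
    """Trainable 2D pixel classifier: filter-bank features + random forest."""

    def __init__(self, estimator, classes: np.ndarray, n_classes: int):
        self.estimator = estimator
        self.classes = np.asarray(classes)
        self.n_classes = int(n_classes)

    def predict(self, image: np.ndarray) -> np.ndarray:
        f = _pixel_features(image)
        flat = f.reshape(f.shape[0], -1).T
        proba = self.estimator.predict_proba(flat)
        scores = np.zeros((self.n_classes, flat.shape[0]))
        for j, c in enumerate(self.classes):
            scores[int(c)] = proba[:, j]
        return scores.reshape((self.n_classes,) + image.shape)


def train_predictor_2d(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
    n_estimators: int = 50,
    samples_per_image: int = 2000,
) -> FilterBankPredictor2D:
    """Train the filter-bank pixel classifier on (image, mask) pairs.

    Pixels are subsampled per image for tractability; deterministic per seed.
    """
    if not pairs:
        raise ValidationError("empty training pair list")
    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for image, mask in pairs:
        image = np.asarray(image)
        mask = np.asarray(mask)
        if image.shape != mask.shape:
            raise ValidationError("image and mask shapes differ in a training pair")
        f = _pixel_features(image).reshape(-1, image.size).T
        lab = mask.ravel()
        n = min(samples_per_image, image.size)
        idx = rng.choice(image.size, size=n, replace=False)
        Xs.append(f[idx])
        ys.append(lab[idx])
    X = np.concatenate(Xs)
    y = np.concatenate(ys).astype(np.int64)
    classes = np.unique(y)
    est = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, class_weight="balanced"
    )
    est.fit(X, y)
    return FilterBankPredictor2D(est, classes=classes, n_classes=int(classes.max()) + 1)
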