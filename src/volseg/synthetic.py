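"""Phantom volumes with exact ground truth.

Generates test volumes containing non-overlapping bright objects — spherical
blobs or straight vessel-like tubes at random orientations — on a constant
background, with optional additive Gaussian noise. The ground-truth labeling
(one id per object), the noisy volume, and the object centroids are all
returned, so every pipeline in the package can be validated end-to-end with
no external data. Placement is rejection sampling with a bounded retry
budget; objects keep at least a two-voxel gap so they stay distinct connected
components. Everything is reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import AnnotationVolume, LabelEntry, LabelTable
from .errors import CapacityError, ValidationError
from .points import PointSet

_MAX_TRIES_PER_OBJECT = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a phantom volume.

    Intensities are in [0, 1] (foreground must differ from background);
    ``radius_range`` bounds the object radius in voxels; ``noise_sigma`` is
    the standard deviation of the additive Gaussian noise.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_objects: int = 5
    kind: str = "blobs"
    fg_intensity: float = 0.8
    bg_intensity: float = 0.2
    radius_range: tuple[float, float] = (4.0, 8.0)
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("blobs", "tubes"):
            raise ValidationError(f"kind must be 'blobs' or 'tubes', got {self.kind!r}")
        if self.fg_intensity == self.bg_intensity:
            raise ValidationError("foreground and background intensities must differ")
        if not (0 <= self.bg_intensity <= 1 and 0 <= self.fg_intensity <= 1):
            raise ValidationError("intensities must lie in [0, 1]")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValidationError(f"bad radius_range {self.radius_range}")
        if self.n_objects < 1:
            raise ValidationError("n_objects must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def _sphere_mask(shape, center, radius):
    lo = [max(0, int(np.floor(center[a] - radius))) for a in range(3)]
    hi = [min(shape[a], int(np.ceil(center[a] + radius)) + 1) for a in range(3)]
    grids = np.meshgrid(*(np.arange(l, h, dtype=np.float64) for l, h in zip(lo, hi)), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    window = tuple(slice(l, h) for l, h in zip(lo, hi))
    return window, d2 <= radius**2


def _place_blobs(spec: PhantomSpec, rng) -> np.ndarray:
    truth = np.zeros(spec.shape, dtype=np.int32)
    placed = []  # (center, radius)
    for obj in range(1, spec.n_objects + 1):
        for _ in range(_MAX_TRIES_PER_OBJECT):
            r = rng.uniform(*spec.radius_range)
            margin = r + 1
            if any(spec.shape[a] - 2 * margin <= 0 for a in range(3)):
                continue
            c = np.array([rng.uniform(margin, spec.shape[a] - margin) for a in range(3)])
            # center-distance check guarantees disjointness with a >=2 voxel gap
            if all(np.linalg.norm(c - pc) >= r + pr + 3 for pc, pr in placed):
                window, mask = _sphere_mask(spec.shape, c, r)
                truth[window][mask] = obj
                placed.append((c, r))
                break
        else:
            raise CapacityError(
                f"could not place object {obj}/{spec.n_objects} in shape {spec.shape}"
            )
    return truth


def _tube_mask(shape, center, direction, radius, half_length):
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    offset = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    t = offset @ direction  # coordinate along the axis
    radial2 = np.sum(offset**2, axis=-1) - t**2
    return (np.abs(t) <= half_length) & (radial2 <= radius**2)


def _place_tubes(spec: PhantomSpec, rng) -> np.ndarray:
    from scipy import ndimage as ndi

    truth = np.zeros(spec.shape, dtype=np.int32)
    occupied = np.zeros(spec.shape, dtype=bool)
    half_length = 0.35 * min(spec.shape)
    for obj in range(1, spec.n_objects + 1):
        for _ in range(_MAX_TRIES_PER_OBJECT):
            r = rng.uniform(*spec.radius_range)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            margin = r + 2
            c = np.array([rng.uniform(margin, spec.shape[a] - margin) for a in range(3)])
            mask = _tube_mask(spec.shape, c, d, r, half_length)
            if not mask.any() or (mask & occupied).any():
                continue
            truth[mask] = obj
            occupied |= ndi.binary_dilation(mask, np.ones((5, 5, 5), dtype=bool))
            break
        else:
            raise CapacityError(
                f"could not place tube {obj}/{spec.n_objects} in shape {spec.shape}"
            )
    return truth


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, PointSet]:
    """Return ``(volume, ground_truth, centroids)``.

    ``ground_truth`` labels each object with its id 1..n (exactly n connected
    components); ``volume`` is the two-intensity image plus Gaussian noise
    (with ``noise_sigma=0`` values are exactly {bg, fg}); centroids are the
    plain voxel-coordinate means, listed in object-id order.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _place_blobs(spec, rng) if spec.kind == "blobs" else _place_tubes(spec, rng)
    volume = np.where(truth > 0, spec.fg_intensity, spec.bg_intensity).astype(np.float64)
    if spec.noise_sigma > 0:
        volume = volume + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    centroids = np.array(
        [np.argwhere(truth == obj).mean(axis=0) for obj in range(1, spec.n_objects + 1)]
    )
    points = PointSet(coords=centroids, class_ids=np.ones(spec.n_objects, dtype=np.int32))
    return volume.astype(np.float32), truth, points


def scribble_from_truth(
    ground_truth: np.ndarray,
    fraction: float,
    seed: int = 0,
    background_label: int | None = None,
) -> AnnotationVolume:
    """Sparse annotation emulating paintbrush scribbles.

    A random ``fraction`` of the voxels of every class present in the truth
    (background included, mapped to its own label id, by default
    ``max(truth) + 1``) is labeled; every class gets at least one voxel.
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    truth = np.asarray(ground_truth)
    rng = np.random.default_rng(seed)
    classes = np.unique(truth)
    if background_label is None:
        background_label = int(truth.max()) + 1
    ann = np.zeros(truth.shape, dtype=np.int32)
    table = LabelTable()
    for c in classes:
        label = background_label if c == 0 else int(c)
        name = "background" if c == 0 else f"class_{c}"
        table.entries.append(LabelEntry(id=label, name=name, color=(255, 255, 255)))
        idx = np.flatnonzero(truth.ravel() == c)
        n_pick = idx.size if fraction == 1 else max(1, int(round(fraction * idx.size)))
        chosen = rng.choice(idx, size=n_pick, replace=False)
        ann.ravel()[chosen] = label
    table.entries.sort(key=lambda e: e.id)
    return AnnotationVolume(labels=ann, table=table)
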