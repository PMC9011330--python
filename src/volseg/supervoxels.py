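"""3D supervoxel over-segmentation.

Partitions a volume into compact, boundary-respecting regions using a
SLIC-family clustering: seeds are placed on a regular grid with spacing
``target_shape``, then voxels are iteratively assigned to the nearest centroid
in a joint (intensity, scaled-space) metric

    d^2 = (delta_i / m)^2 + (dz^2 + dy^2 + dx^2) / S^2

where ``m`` is the compactness, ``S`` the mean target spacing and the search
window extends ``target_shape`` voxels either side of each centroid (the
standard 2S window). Intensity differences are measured on an 8-bit (0-255)
scale so that the customary compactness values of the SLIC literature apply
directly to volumes normalized to [0, 1]; the default compactness is 30.

After the final iteration, connectivity is enforced: any 26-connected
fragment of a supervoxel other than its largest component is merged into the
largest 26-adjacent neighboring supervoxel (ties broken by smallest label id),
and labels are re-packed to the contiguous range ``[0, K)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError

_INTENSITY_SCALE = 255.0
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SupervoxelParams:
    """Parameters of the supervoxel clustering.

    target_shape : voxels per supervoxel edge (z, y, x); default 10x10x10.
    compactness  : spatial-vs-intensity weight on the 8-bit intensity scale.
    n_iter       : number of assignment/update iterations.
    """

    target_shape: tuple[int, int, int] = (10, 10, 10)
    compactness: float = 30.0
    n_iter: int = 10

    def __post_init__(self) -> None:
        if len(self.target_shape) != 3 or any(t < 2 for t in self.target_shape):
            raise ValidationError(f"target_shape must be 3 integers >= 2, got {self.target_shape}")
        if self.compactness <= 0:
            raise ValidationError("compactness must be positive")
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")


@dataclass
class SupervoxelPartition:
    """A complete labeling of a volume into K connected supervoxels."""

    labels: np.ndarray
    count: int
    params: SupervoxelParams
    source_layer: str | None = field(default=None)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)


def _grid_seeds(shape, target_shape):
    """Seed coordinates at the centers of a regular block grid."""
    axes = []
    for dim, t in zip(shape, target_shape):
        n = max(1, int(round(dim / t)))
        axes.append((np.arange(n) + 0.5) * dim / n - 0.5)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)


def compute_supervoxels(
    volume: np.ndarray,
    params: SupervoxelParams = SupervoxelParams(),
    source_layer: str | None = None,
) -> SupervoxelPartition:
    """Cluster ``volume`` (expected in [0, 1]) into supervoxels.

    Deterministic: identical input and parameters give an identical labeling.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {volume.shape}")
    if not np.all(np.isfinite(volume)):
        raise ValidationError("volume contains non-finite values")
    shape = volume.shape
    tshape = tuple(int(t) for t in params.target_shape)
    if any(t > s for t, s in zip(tshape, shape)):
        raise ValidationError(
            f"target_shape {tshape} exceeds volume shape {shape} on some axis"
        )

    intensity = volume * _INTENSITY_SCALE
    seeds = _grid_seeds(shape, tshape)
    n_seeds = len(seeds)
    centroids = seeds.copy()  # (K, 3) float
    seed_idx = tuple(np.clip(np.round(seeds[:, a]).astype(int), 0, shape[a] - 1) for a in range(3))
    cent_int = intensity[seed_idx].astype(np.float64)

    S = float(np.mean(tshape))
    m = float(params.compactness)
    coords = [np.arange(s, dtype=np.float64) for s in shape]

    labels = np.full(shape, -1, dtype=np.int32)
    for _ in range(params.n_iter):
        dist = np.full(shape, np.inf)
        labels.fill(-1)
        for k in range(n_seeds):
            lo = [max(0, int(np.floor(centroids[k, a] - tshape[a]))) for a in range(3)]
            hi = [min(shape[a], int(np.ceil(centroids[k, a] + tshape[a])) + 1) for a in range(3)]
            win = tuple(slice(l, h) for l, h in zip(lo, hi))
            dz = (coords[0][win[0]] - centroids[k, 0]) ** 2
            dy = (coords[1][win[1]] - centroids[k, 1]) ** 2
            dx = (coords[2][win[2]] - centroids[k, 2]) ** 2
            spatial = (dz[:, None, None] + dy[None, :, None] + dx[None, None, :]) / S**2
            di = (intensity[win] - cent_int[k]) / m
            d2 = di * di + spatial
            better = d2 < dist[win]
            dist[win][better] = d2[better]
            lw = labels[win]
            lw[better] = k
            labels[win] = lw
        if np.any(labels < 0):  # centroids drifted and left coverage gaps
            _, (iz, iy, ix) = ndi.distance_transform_edt(labels < 0, return_indices=True)
            labels = labels[iz, iy, ix]
        # centroid update
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=n_seeds).astype(np.float64)
        nonzero = counts > 0
        zz, yy, xx = np.meshgrid(*coords, indexing="ij")
        for a, grid in enumerate((zz, yy, xx)):
            sums = np.bincount(flat, weights=grid.ravel(), minlength=n_seeds)
            centroids[nonzero, a] = sums[nonzero] / counts[nonzero]
        isums = np.bincount(flat, weights=intensity.ravel(), minlength=n_seeds)
        cent_int[nonzero] = isums[nonzero] / counts[nonzero]

    labels = _enforce_connectivity(labels, n_seeds)
    _, packed = np.unique(labels, return_inverse=True)
    labels = packed.reshape(shape).astype(np.int32)
    return SupervoxelPartition(
        labels=labels, count=int(labels.max()) + 1, params=params, source_layer=source_layer
    )


def _enforce_connectivity(labels: np.ndarray, n_labels: int, max_passes: int = 50) -> np.ndarray:
    """Merge every non-largest 26-connected fragment of each label into its
    largest 26-adjacent neighboring supervoxel (ties -> smallest label id).

    A merge can extend a label beyond the bounding box recorded before the
    pass, so passes repeat with fresh bounding boxes until every label is a
    single component; the total fragment count decreases monotonically."""
    labels = labels.copy()
    for _ in range(max_passes):
        changed = False
        volumes = np.bincount(labels.ravel(), minlength=n_labels).astype(np.int64)
        objects = ndi.find_objects(labels + 1)  # find_objects needs labels >= 1
        for lab in range(n_labels):
            sl = objects[lab]
            if sl is None:
                continue
            # pad bbox by 1 for neighbor lookup
            padded = tuple(
                slice(max(0, s.start - 1), min(dim, s.stop + 1))
                for s, dim in zip(sl, labels.shape)
            )
            sub = labels[padded]
            cc, n_cc = ndi.label(sub == lab, structure=_STRUCT26)
            if n_cc <= 1:
                continue
            sizes = ndi.sum_labels(np.ones_like(cc), cc, index=np.arange(1, n_cc + 1))
            keep = int(np.argmax(sizes)) + 1  # first max -> deterministic
            for frag in range(1, n_cc + 1):
                if frag == keep:
                    continue
                frag_mask = cc == frag
                ring = ndi.binary_dilation(frag_mask, structure=_STRUCT26) & ~frag_mask
                neighbor_labels = np.unique(sub[ring])
                neighbor_labels = neighbor_labels[neighbor_labels != lab]
                if len(neighbor_labels) == 0:
                    continue
                # largest neighbor by global supervoxel volume; ties -> smallest id
                vols = volumes[neighbor_labels]
                target = int(neighbor_labels[np.argmax(vols)])
                n_moved = int(frag_mask.sum())
                sub[frag_mask] = target
                volumes[target] += n_moved
                volumes[lab] -= n_moved
                changed = True
        if not changed:
            break
    return labels


def summarize_partition(partition: SupervoxelPartition) -> dict:
    """Count and volume statistics; per-supervoxel volumes sum to the voxel count."""
    volumes = np.bincount(partition.labels.ravel(), minlength=partition.count)
    return {
        "count": int(partition.count),
        "mean_volume": float(volumes.mean()),
        "min_volume": int(volumes.min()),
        "max_volume": int(volumes.max()),
    }


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels that differ from at least one 6-neighbor (supervoxel boundaries)."""
    mask = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        diff = np.diff(labels, axis=axis) != 0
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        mask[tuple(lo)] |= diff
        mask[tuple(hi)] |= diff
    return mask
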