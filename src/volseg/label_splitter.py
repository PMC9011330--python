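"""Object-level analysis: connected components, shape/intensity measurement,
and sequential rule-based splitting of objects into classes.

Starting from any integer segmentation, the splitter finds 3D connected
components of the foreground (6- or 26-connectivity, default 26), measures a
descriptor per object — intensity statistics, voxel volume, axis-aligned
bounding-box extents and volume (plus natural log), centroid position, and an
oriented bounding box derived from the principal axes of the voxel-coordinate
covariance — then applies an ordered list of threshold rules. Every object
starts at a default class, each rule reassigns the objects satisfying its
predicate, and later rules override earlier ones (last writer wins). The
splitter composes: reapplying it to the objects of one class never touches
objects outside that class.

Extent conventions: bounding boxes use the voxel-as-cell convention
(``max - min + 1``), so a single voxel has unit extents in both the
axis-aligned and the oriented box; oriented extents are sorted descending as
(depth, height, width). "Variation of intensity" is exported as the variance
(sd^2) alongside the standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ValidationError

COMPARATORS = {
    ">": np.greater,
    "<": np.less,
    ">=": np.greater_equal,
    "<=": np.less_equal,
    "≥": np.greater_equal,  # ≥
    "≤": np.less_equal,  # ≤
}

MEASUREMENT_COLUMNS = [
    "object_id",
    "mean_intensity",
    "sd_intensity",
    "var_intensity",
    "volume",
    "bbox_volume",
    "log_bbox_volume",
    "position_z",
    "position_y",
    "position_x",
    "bbox_depth",
    "bbox_height",
    "bbox_width",
    "obb_volume",
    "log_obb_volume",
    "obb_depth",
    "obb_height",
    "obb_width",
]


@dataclass(frozen=True)
class SplitRule:
    """One threshold rule: objects with ``feature <comparator> threshold``
    are (re)assigned to ``class_id``."""

    feature: str
    comparator: str
    threshold: float
    class_id: int

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValidationError(
                f"unknown comparator {self.comparator!r}; expected one of {sorted(COMPARATORS)}"
            )


def extract_objects(
    segmentation: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, np.ndarray]:
    """Label 3D connected components of the nonzero foreground.

    Returns ``(objects, ids)`` where objects is an int32 volume with ids
    ``1..M`` in deterministic scan order and ids is the array ``[1..M]``.
    """
    segmentation = np.asarray(segmentation)
    if not np.issubdtype(segmentation.dtype, np.integer):
        raise ValidationError(f"segmentation must be integer-valued, got dtype {segmentation.dtype}")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndi.generate_binary_structure(3, 1)
    else:
        raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")
    objects, n = ndi.label(segmentation != 0, structure=structure)
    return objects.astype(np.int32), np.arange(1, n + 1, dtype=np.int32)


def _oriented_extents(coords: np.ndarray) -> np.ndarray:
    """Extents of the voxel set along its principal axes, sorted descending.

    Principal axes are the eigenvectors of the coordinate covariance; each
    extent is max - min + 1 of the projected coordinates (voxel-as-cell).
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) == 1:
        return np.ones(3)
    cov = np.cov(centered.T)
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0
    return np.sort(extents)[::-1]


def measure_objects(objects: np.ndarray, intensity_volume: np.ndarray) -> pd.DataFrame:
    """One measurement record per object; see module docstring for conventions."""
    objects = np.asarray(objects)
    intensity_volume = np.asarray(intensity_volume, dtype=np.float64)
    if objects.shape != intensity_volume.shape:
        raise ValidationError(
            f"objects shape {objects.shape} != intensity shape {intensity_volume.shape}"
        )
    slices = ndi.find_objects(objects)
    records = []
    for obj_id, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = objects[sl] == obj_id
        vals = intensity_volume[sl][sub]
        volume = int(sub.sum())
        coords = np.argwhere(sub).astype(np.float64)
        coords += np.array([s.start for s in sl], dtype=np.float64)
        centroid = coords.mean(axis=0)
        bbox_dims = coords.max(axis=0) - coords.min(axis=0) + 1.0
        bbox_volume = float(np.prod(bbox_dims))
        obb = _oriented_extents(coords)
        obb_volume = float(np.prod(obb))
        mean = float(vals.mean())
        var = float(vals.var())
        records.append(
            {
                "object_id": obj_id,
                "mean_intensity": mean,
                "sd_intensity": float(np.sqrt(var)),
                "var_intensity": var,
                "volume": volume,
                "bbox_volume": bbox_volume,
                "log_bbox_volume": float(np.log(bbox_volume)),
                "position_z": float(centroid[0]),
                "position_y": float(centroid[1]),
                "position_x": float(centroid[2]),
                "bbox_depth": float(bbox_dims[0]),
                "bbox_height": float(bbox_dims[1]),
                "bbox_width": float(bbox_dims[2]),
                "obb_volume": obb_volume,
                "log_obb_volume": float(np.log(obb_volume)),
                "obb_depth": float(obb[0]),
                "obb_height": float(obb[1]),
                "obb_width": float(obb[2]),
            }
        )
    return pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)


def apply_rules(
    table: pd.DataFrame,
    rules: list[SplitRule],
    default_class: int = 0,
) -> dict[int, int]:
    """Sequentially apply rules; later rules override earlier assignments."""
    for rule in rules:
        if rule.feature not in table.columns:
            raise ValidationError(f"unknown feature {rule.feature!r} in rule")
    classes = np.full(len(table), int(default_class), dtype=np.int64)
    for rule in rules:
        hit = COMPARATORS[rule.comparator](table[rule.feature].to_numpy(), rule.threshold)
        classes[hit] = int(rule.class_id)
    return {int(oid): int(c) for oid, c in zip(table["object_id"], classes)}


def classes_to_volume(objects: np.ndarray, class_map: dict[int, int]) -> np.ndarray:
    """Relabel each object voxel with its class; background stays 0."""
    objects = np.asarray(objects)
    present = np.unique(objects)
    present = present[present != 0]
    missing = [int(i) for i in present if int(i) not in class_map]
    if missing:
        raise ValidationError(f"class map missing object id(s) {missing}")
    lut = np.zeros(int(objects.max()) + 1, dtype=np.int32)
    for oid, cls in class_map.items():
        if oid <= 0 or oid >= len(lut):
            continue
        lut[oid] = cls
    return lut[objects]


def rules_from_json(items: list[dict]) -> list[SplitRule]:
    """Parse the on-disk rule format: a list of
    ``{"feature", "comparator", "threshold", "class"}`` objects."""
    rules = []
    for i, d in enumerate(items):
        try:
            rules.append(
                SplitRule(
                    feature=d["feature"],
                    comparator=d["comparator"],
                    threshold=float(d["threshold"]),
                    class_id=int(d["class"]),
                )
            )
        except KeyError as exc:
            raise ValidationError(f"rule {i}: missing key {exc}") from exc
    return rules
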