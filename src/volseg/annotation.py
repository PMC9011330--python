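"""Label tables with a parent-child hierarchy, and programmatic painting.

Labels are positive integers; 0 is reserved for "unlabeled". Each label may
name a parent label, forming a forest, and a child annotation layer can be
clipped so that child voxels never escape the parent's mask
(:func:`restrict_to_parent`). Painting assigns whole supervoxels at a time —
the unit of interactive annotation — and always overwrites whatever the
touched voxels held before; painting with label 0 erases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .supervoxels import SupervoxelPartition


@dataclass
class LabelEntry:
    id: int
    name: str
    color: tuple[int, int, int]
    parent_id: int | None = None

    def to_dict(self) -> dict:
        return {"id": self.id, "name": self.name, "color": list(self.color), "parent_id": self.parent_id}

    @classmethod
    def from_dict(cls, d: dict) -> "LabelEntry":
        return cls(d["id"], d["name"], tuple(d["color"]), d.get("parent_id"))


@dataclass
class LabelTable:
    """Ordered set of label definitions. Colors are metadata only."""

    entries: list[LabelEntry] = field(default_factory=list)

    def ids(self) -> set[int]:
        return {e.id for e in self.entries}

    def get(self, label_id: int) -> LabelEntry:
        for e in self.entries:
            if e.id == label_id:
                return e
        raise ValidationError(f"unknown label id {label_id}")

    def to_list(self) -> list[dict]:
        return [e.to_dict() for e in self.entries]

    @classmethod
    def from_list(cls, items: list[dict]) -> "LabelTable":
        return cls([LabelEntry.from_dict(d) for d in items])


def define_label(
    table: LabelTable,
    name: str,
    color: tuple[int, int, int] = (255, 255, 255),
    parent_id: int | None = None,
) -> int:
    """Add a label; the new id is ``max(existing ids) + 1`` (first label -> 1)."""
    if any(e.name == name for e in table.entries):
        raise ValidationError(f"duplicate label name {name!r}")
    if parent_id is not None and parent_id not in table.ids():
        raise ValidationError(f"parent label {parent_id} does not exist")
    new_id = max(table.ids(), default=0) + 1
    table.entries.append(LabelEntry(id=new_id, name=name, color=tuple(color), parent_id=parent_id))
    return new_id


@dataclass
class AnnotationVolume:
    """A 3D integer label volume (0 = unlabeled) plus its label table."""

    labels: np.ndarray
    table: LabelTable

    @classmethod
    def empty(cls, shape: tuple[int, int, int], table: LabelTable | None = None) -> "AnnotationVolume":
        return cls(np.zeros(shape, dtype=np.int32), table or LabelTable())

    def check_invariants(self) -> None:
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - self.table.ids()
        if missing:
            raise ValidationError(f"annotation contains undefined label ids {sorted(missing)}")


def paint_supervoxels(
    ann: AnnotationVolume,
    partition: SupervoxelPartition,
    supervoxel_ids,
    label_id: int,
) -> AnnotationVolume:
    """Set every voxel of the named supervoxels to ``label_id`` (0 erases).

    Overwrites any previous label in the touched supervoxels; voxels outside
    them are never modified. Returns ``ann`` (mutated in place).
    """
    if ann.labels.shape != partition.labels.shape:
        raise ValidationError("annotation and partition shapes differ")
    if label_id != 0:
        ann.table.get(label_id)  # raises for unknown labels
    ids = np.asarray(sorted(set(int(i) for i in supervoxel_ids)), dtype=np.int64)
    if len(ids) and (ids.min() < 0 or ids.max() >= partition.count):
        bad = ids[(ids < 0) | (ids >= partition.count)]
        raise ValidationError(f"supervoxel id(s) {bad.tolist()} outside [0, {partition.count})")
    mask = np.isin(partition.labels, ids)
    ann.labels[mask] = label_id
    return ann


def restrict_to_parent(
    child_ann: AnnotationVolume,
    parent_ann: AnnotationVolume,
    label_id: int,
) -> AnnotationVolume:
    """Clear voxels of ``label_id`` that lie outside its parent's mask.

    If the label has no parent this is a no-op and emits a warning. Returns
    ``child_ann`` (mutated in place).
    """
    entry = child_ann.table.get(label_id)
    if entry.parent_id is None:
        warnings.warn(f"label {label_id} ({entry.name!r}) has no parent; restrict is a no-op")
        return child_ann
    if child_ann.labels.shape != parent_ann.labels.shape:
        raise ValidationError("child and parent annotation shapes differ")
    parent_mask = parent_ann.labels == entry.parent_id
    escape = (child_ann.labels == label_id) & ~parent_mask
    child_ann.labels[escape] = 0
    return child_ann
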