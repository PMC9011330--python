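"""On-disk workspace for volumetric segmentation projects.

A workspace is a directory holding every volume-sized artifact of a
segmentation project — the raw volume, feature layers, supervoxel partitions,
annotations and predictions — each stored as its own chunked HDF5 file under a
kind-named subdirectory, plus a JSON metadata document and a serializable
session (the ordered parameter sets of every pipeline stage that has been run).

Conventions
-----------
* Axis order is ``(z, y, x)`` = (slice, row, column), 0-based.
* Regions of interest (:class:`ROI`) are half-open boxes.
* The raw volume is min-max rescaled to ``[0, 1]`` on import; a constant
  volume maps to 0.
* Default chunk shape is ``(32, 128, 128)``, clipped to the volume shape, and
  can be overridden globally at creation time.
"""

from __future__ import annotations

import datetime
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .errors import ConflictError, ValidationError

METADATA_FILE = "workspace.json"
SESSION_FILE = "session.yaml"
DEFAULT_CHUNK_SHAPE = (32, 128, 128)

#: layer kinds and the dtypes they are stored with
LAYER_KINDS = {
    "raw": "float32",
    "feature": "float32",
    "supervoxels": "int32",
    "annotation": "uint8",
    "prediction": "int32",
    "objects": "int32",
}
INTEGER_KINDS = frozenset({"supervoxels", "annotation", "prediction", "objects"})


@dataclass(frozen=True)
class ROI:
    """Half-open axis-aligned box ``[start, stop)`` in (z, y, x) voxel indices."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.start) != 3 or len(self.stop) != 3:
            raise ValidationError("ROI start/stop must be 3-tuples")
        if any(a < 0 for a in self.start):
            raise ValidationError(f"ROI start must be non-negative, got {self.start}")
        if not all(a < b for a, b in zip(self.start, self.stop)):
            raise ValidationError(f"ROI start must be < stop elementwise: {self.start} vs {self.stop}")

    def validate_within(self, shape: tuple[int, int, int]) -> None:
        if not all(b <= s for b, s in zip(self.stop, shape)):
            raise ValidationError(f"ROI stop {self.stop} exceeds volume shape {shape}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "ROI":
        return cls((0, 0, 0), tuple(int(s) for s in shape))


@dataclass(frozen=True)
class LayerInfo:
    """Descriptor of one stored layer."""

    name: str
    kind: str
    dtype: str
    chunk_shape: tuple[int, int, int]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "dtype": self.dtype,
            "chunk_shape": list(self.chunk_shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerInfo":
        return cls(d["name"], d["kind"], d["dtype"], tuple(d["chunk_shape"]))


def _check_layer_name(name: str) -> None:
    if not name or not all(c.isalnum() or c in "_-" for c in name):
        raise ValidationError(
            f"layer name {name!r} must be non-empty and contain only [A-Za-z0-9_-]"
        )


def rescale_minmax(volume: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant volume maps to all zeros."""
    volume = np.asarray(volume, dtype=np.float64)
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        return np.zeros(volume.shape, dtype=np.float32)
    return ((volume - lo) / (hi - lo)).astype(np.float32)


@dataclass
class Workspace:
    """Handle to an on-disk workspace.

    Obtain instances through :func:`create_workspace` or :func:`open_workspace`;
    the constructor does not touch the disk.
    """

    root_path: Path
    metadata: dict = field(default_factory=dict)
    layers: list[LayerInfo] = field(default_factory=list)
    chunk_shape: tuple[int, int, int] = DEFAULT_CHUNK_SHAPE
    base_shape: tuple[int, int, int] = (0, 0, 0)
    session: dict = field(default_factory=lambda: {"stages": []})
    label_tables: dict = field(default_factory=dict)

    # -- persistence ------------------------------------------------------

    def _meta_path(self) -> Path:
        return self.root_path / METADATA_FILE

    def save_metadata(self) -> None:
        doc = {
            "metadata": self.metadata,
            "base_shape": list(self.base_shape),
            "chunk_shape": list(self.chunk_shape),
            "layers": [li.to_dict() for li in self.layers],
            "label_tables": self.label_tables,
        }
        self._meta_path().write_text(json.dumps(doc, indent=2, sort_keys=True))

    # -- layer management -------------------------------------------------

    def layer_info(self, name: str) -> LayerInfo:
        for li in self.layers:
            if li.name == name:
                return li
        raise ValidationError(f"unknown layer {name!r}")

    def has_layer(self, name: str) -> bool:
        return any(li.name == name for li in self.layers)

    def list_layers(self) -> list[LayerInfo]:
        return list(self.layers)

    def layer_path(self, name: str) -> Path:
        li = self.layer_info(name)
        return self.root_path / li.kind / f"{li.name}.h5"

    def add_layer(self, name: str, kind: str, volume: np.ndarray) -> LayerInfo:
        """Persist ``volume`` as a new chunked layer.

        Integer kinds (supervoxels/annotation/prediction/objects) reject float
        data; float kinds are stored as float32.
        """
        _check_layer_name(name)
        if self.has_layer(name):
            raise ConflictError(f"layer {name!r} already exists")
        if kind not in LAYER_KINDS:
            raise ValidationError(f"unknown layer kind {kind!r}; expected one of {sorted(LAYER_KINDS)}")
        volume = np.asarray(volume)
        if volume.ndim != 3:
            raise ValidationError(f"layer data must be 3D, got ndim={volume.ndim}")
        if tuple(volume.shape) != self.base_shape:
            raise ValidationError(
                f"layer shape {volume.shape} does not match workspace shape {self.base_shape}"
            )
        if kind in INTEGER_KINDS:
            if not np.issubdtype(volume.dtype, np.integer):
                raise ValidationError(f"kind {kind!r} requires integer data, got dtype {volume.dtype}")
            dtype = LAYER_KINDS[kind]
            if kind == "annotation" and (volume.min() < 0 or volume.max() > 255):
                dtype = "int32"
        else:
            dtype = LAYER_KINDS[kind]
        chunk = tuple(min(c, s) for c, s in zip(self.chunk_shape, self.base_shape))
        li = LayerInfo(name=name, kind=kind, dtype=dtype, chunk_shape=chunk)
        path = self.root_path / kind / f"{name}.h5"
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=volume.astype(dtype), chunks=chunk)
        self.layers.append(li)
        self.save_metadata()
        return li

    def write_layer(self, name: str, volume: np.ndarray) -> None:
        """Overwrite the full data of an existing layer (dtype/kind preserved)."""
        li = self.layer_info(name)
        volume = np.asarray(volume)
        if tuple(volume.shape) != self.base_shape:
            raise ValidationError(
                f"layer shape {volume.shape} does not match workspace shape {self.base_shape}"
            )
        with h5py.File(self.layer_path(name), "r+") as f:
            f["data"][...] = volume.astype(li.dtype)

    def delete_layer(self, name: str) -> None:
        path = self.layer_path(name)
        path.unlink(missing_ok=True)
        self.layers = [li for li in self.layers if li.name != name]
        self.save_metadata()

    def read_region(self, name: str, roi: ROI) -> np.ndarray:
        """Read the half-open box ``roi`` from a layer."""
        li = self.layer_info(name)
        roi.validate_within(self.base_shape)
        with h5py.File(self.layer_path(name), "r") as f:
            return np.asarray(f["data"][roi.slices], dtype=li.dtype)

    def read_layer(self, name: str) -> np.ndarray:
        return self.read_region(name, ROI.full(self.base_shape))

    # -- session ----------------------------------------------------------

    def record_stage(self, operation: str, params: dict) -> None:
        """Append one executed pipeline stage (operation name + parameters)."""
        self.session["stages"].append({"operation": operation, "params": params})

    def save_session(self) -> dict:
        """Serialize recorded pipeline parameters to ``session.yaml``; return the document."""
        doc = {"stages": self.session["stages"]}
        (self.root_path / SESSION_FILE).write_text(yaml.safe_dump(doc, sort_keys=False))
        return doc

    def load_saved_session(self) -> dict:
        path = self.root_path / SESSION_FILE
        if not path.exists():
            return {"stages": []}
        try:
            doc = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ValidationError(f"corrupt session file {path}: {exc}") from exc
        if not isinstance(doc, dict) or "stages" not in doc:
            raise ValidationError(f"corrupt session file {path}: missing key 'stages'")
        return doc


def create_workspace(
    root_path,
    volume: np.ndarray,
    name: str = "workspace",
    chunk_shape: tuple[int, int, int] = DEFAULT_CHUNK_SHAPE,
    overwrite: bool = False,
) -> Workspace:
    """Create a workspace at ``root_path`` from a 3D imaging volume.

    The volume is min-max rescaled to [0, 1] and stored as a layer named
    ``"raw"``. Refuses to clobber an existing workspace unless ``overwrite``.
    """
    root = Path(root_path)
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.size == 0:
        raise ValidationError(f"volume must be non-empty and 3D, got shape {volume.shape}")
    if not np.all(np.isfinite(volume)):
        raise ValidationError("volume contains non-finite values")
    if (root / METADATA_FILE).exists():
        if not overwrite:
            raise ConflictError(f"workspace already exists at {root}")
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)
    ws = Workspace(
        root_path=root,
        metadata={
            "name": name,
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        chunk_shape=tuple(int(c) for c in chunk_shape),
        base_shape=tuple(int(s) for s in volume.shape),
    )
    ws.save_metadata()
    ws.add_layer("raw", "raw", rescale_minmax(volume))
    return ws


def open_workspace(root_path) -> Workspace:
    """Open an existing workspace, restoring metadata, layers and session."""
    root = Path(root_path)
    meta_path = root / METADATA_FILE
    if not meta_path.exists():
        raise ValidationError(f"no workspace at {root}")
    try:
        doc = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"corrupt workspace metadata: {exc}") from exc
    ws = Workspace(
        root_path=root,
        metadata=doc["metadata"],
        layers=[LayerInfo.from_dict(d) for d in doc["layers"]],
        chunk_shape=tuple(doc["chunk_shape"]),
        base_shape=tuple(doc["base_shape"]),
        label_tables=doc.get("label_tables", {}),
    )
    ws.session = ws.load_saved_session()
    return ws


# -- import / export -------------------------------------------------------


def load_volume(path, dataset: str | None = None) -> np.ndarray:
    """Load a 3D volume from an HDF5 file (``dataset`` names the array) or a TIFF stack."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        with h5py.File(path, "r") as f:
            if dataset is None:
                keys = list(f.keys())
                if len(keys) != 1:
                    raise ValidationError(
                        f"HDF5 file has datasets {keys}; specify one with dataset="
                    )
                dataset = keys[0]
            if dataset not in f:
                raise ValidationError(f"dataset {dataset!r} not found in {path}")
            vol = np.asarray(f[dataset])
    elif path.suffix.lower() in {".tif", ".tiff"}:
        vol = np.asarray(tifffile.imread(path))
    else:
        raise ValidationError(f"unsupported volume format {path.suffix!r}")
    if vol.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {vol.shape}")
    return vol


def export_layer(ws: Workspace, layer: str, out_path, dataset: str = "data") -> None:
    """Export a layer to HDF5 or TIFF depending on the output suffix."""
    data = ws.read_layer(layer)
    out = Path(out_path)
    if out.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        with h5py.File(out, "w") as f:
            f.create_dataset(dataset, data=data)
    elif out.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(out, data)
    else:
        raise ValidationError(f"unsupported export format {out.suffix!r}")
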