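"""Declarative pipeline execution over a workspace.

A pipeline config is an ordered list of stages, each naming a registered
operation and its parameters, plus one global seed that fixes every
stochastic stage. Configs round-trip through YAML unchanged, are fully
validated before any stage executes, and every run appends its stages to the
workspace session so that :meth:`Workspace.save_session` can replay the same
processing on a naive volume of the same shape.

Registered operations:

``filter``
    Apply a registry filter to a layer. params: ``name``, ``in`` (default
    ``raw``), ``out``, ``params`` (filter parameter map).
``supervoxels``
    params: ``in``, ``out``, ``target_shape``, ``compactness``, ``n_iter``.
``scribble``
    Sparse annotation sampled from an integer layer (phantom truth or a
    previous prediction). params: ``truth`` (layer), ``fraction``, ``out``.
``shallow``
    Supervoxel classifier segmentation. params: ``ann``, ``sv``,
    ``features`` (list of layers), ``kind``, ``out``, optional ``params``.
``deep``
    Train the 2D filter-bank predictor on (data, labels) slice pairs from an
    optional ROI and vote-fuse predictions over the full volume. params:
    ``data``, ``labels``, optional ``roi`` ([z0,z1,y0,y1,x0,x1]),
    ``rotations``, ``out``.
``rasterize``
    Paint ellipsoids at CSV points. params: ``csv``, ``radii``, optional
    ``orientation``, ``out``, optional ``acwe`` (bool), ``acwe_iters``,
    ``intensity`` layer.
``label_split``
    Connected components + measurements + rules. params: ``seg``,
    ``intensity``, ``rules`` (list of rule dicts), ``default_class``,
    ``connectivity``, ``out``.
"""

from __future__ import annotations

import json
import time

import numpy as np
import yaml

from . import filters, label_splitter, multiaxis, points, shallow, supervoxels
from .annotation import AnnotationVolume, LabelTable
from .errors import ValidationError
from .synthetic import scribble_from_truth
from .workspace import ROI, Workspace

REPORT_FILE = "report.json"


class PipelineError(RuntimeError):
    """A stage failed; ``report`` flags completed and partial outputs."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


# -- per-stage validation and execution ------------------------------------


def _require(params: dict, *keys):
    missing = [k for k in keys if k not in params]
    if missing:
        raise ValidationError(f"missing required parameter(s) {missing}")


def _validate_filter(params):
    _require(params, "name", "out")
    known = filters.list_filters()
    if params["name"] not in known:
        raise ValidationError(f"unknown filter name {params['name']!r}")


def _run_filter(ws: Workspace, params, seed):
    spec = filters.FilterSpec(name=params["name"], params=dict(params.get("params", {})))
    data = ws.read_layer(params.get("in", "raw"))
    ws.add_layer(params["out"], "feature", filters.apply_filter(data, spec))
    return [params["out"]]


def _validate_supervoxels(params):
    _require(params, "in", "out")


def _run_supervoxels(ws, params, seed):
    sv_params = supervoxels.SupervoxelParams(
        target_shape=tuple(params.get("target_shape", (10, 10, 10))),
        compactness=float(params.get("compactness", 30.0)),
        n_iter=int(params.get("n_iter", 10)),
    )
    part = supervoxels.compute_supervoxels(
        ws.read_layer(params["in"]), sv_params, source_layer=params["in"]
    )
    ws.add_layer(params["out"], "supervoxels", part.labels)
    return [params["out"]]


def _validate_scribble(params):
    _require(params, "truth", "out")


def _run_scribble(ws, params, seed):
    truth = ws.read_layer(params["truth"])
    ann = scribble_from_truth(truth, float(params.get("fraction", 0.05)), seed=seed)
    ws.add_layer(params["out"], "annotation", ann.labels)
    ws.label_tables[params["out"]] = ann.table.to_list()
    ws.save_metadata()
    return [params["out"]]


def _validate_shallow(params):
    _require(params, "ann", "sv", "features", "out")
    if not params["features"]:
        raise ValidationError("shallow stage needs at least one feature layer")
    kind = params.get("kind", "random_forest")
    if kind not in shallow.CLASSIFIER_KINDS:
        raise ValidationError(f"unknown classifier kind {kind!r}")


def _run_shallow(ws, params, seed):
    sv_labels = ws.read_layer(params["sv"])
    part = supervoxels.SupervoxelPartition(
        labels=sv_labels,
        count=int(sv_labels.max()) + 1,
        params=supervoxels.SupervoxelParams(),
        source_layer=params["sv"],
    )
    table = LabelTable.from_list(ws.label_tables.get(params["ann"], []))
    ann = AnnotationVolume(labels=ws.read_layer(params["ann"]), table=table)
    feature_layers = {name: ws.read_layer(name) for name in params["features"]}
    pred = shallow.segment(
        feature_layers,
        part,
        ann,
        kind=params.get("kind", "random_forest"),
        params=params.get("params"),
        seed=seed,
    )
    ws.add_layer(params["out"], "prediction", pred)
    return [params["out"]]


def _validate_deep(params):
    _require(params, "data", "labels", "out")
    bad = set(int(r) for r in params.get("rotations", [])) - set(multiaxis.VALID_ROTATIONS)
    if bad:
        raise ValidationError(f"invalid rotation(s) {sorted(bad)}")


def _run_deep(ws, params, seed):
    data = ws.read_layer(params["data"])
    labels = ws.read_layer(params["labels"])
    if "roi" in params:
        r = [int(v) for v in params["roi"]]
        roi = ROI((r[0], r[2], r[4]), (r[1], r[3], r[5]))
        roi.validate_within(ws.base_shape)
        train_data, train_labels = data[roi.slices], labels[roi.slices]
    else:
        train_data, train_labels = data, labels
    pairs = multiaxis.make_training_pairs(train_data, train_labels)
    predictor = multiaxis.train_predictor_2d(pairs, seed=seed)
    fused = multiaxis.predict_fuse(
        predictor, data, rotations=tuple(int(r) for r in params.get("rotations", ()))
    )
    ws.add_layer(params["out"], "prediction", fused.astype(np.int32))
    return [params["out"]]


def _validate_rasterize(params):
    _require(params, "csv", "radii", "out")


def _run_rasterize(ws, params, seed):
    ps = points.read_points_csv(params["csv"])
    spec = points.EllipsoidSpec(
        radii=tuple(float(r) for r in params["radii"]),
        orientation=tuple(float(a) for a in params.get("orientation", (0, 0, 0))),
    )
    mask = points.rasterize_points(ps, spec, ws.base_shape)
    if params.get("acwe"):
        refined = points.acwe_refine(
            mask > 0,
            ws.read_layer(params.get("intensity", "raw")),
            iters=int(params.get("acwe_iters", 30)),
        )
        mask = np.where(refined > 0, mask.max(initial=1), 0).astype(np.int32)
    ws.add_layer(params["out"], "annotation", mask)
    return [params["out"]]


def _validate_label_split(params):
    _require(params, "seg", "out")
    label_splitter.rules_from_json(params.get("rules", []))


def _run_label_split(ws, params, seed):
    seg = ws.read_layer(params["seg"])
    objects, _ = label_splitter.extract_objects(seg, int(params.get("connectivity", 26)))
    table = label_splitter.measure_objects(objects, ws.read_layer(params.get("intensity", "raw")))
    rules = label_splitter.rules_from_json(params.get("rules", []))
    class_map = label_splitter.apply_rules(table, rules, int(params.get("default_class", 0)))
    ws.add_layer(params["out"], "objects", label_splitter.classes_to_volume(objects, class_map))
    if "table_csv" in params:
        table.to_csv(params["table_csv"], index=False)
    return [params["out"]]


STAGE_REGISTRY = {
    "filter": (_validate_filter, _run_filter),
    "supervoxels": (_validate_supervoxels, _run_supervoxels),
    "scribble": (_validate_scribble, _run_scribble),
    "shallow": (_validate_shallow, _run_shallow),
    "deep": (_validate_deep, _run_deep),
    "rasterize": (_validate_rasterize, _run_rasterize),
    "label_split": (_validate_label_split, _run_label_split),
}


def validate_config(config: dict) -> None:
    """Check every stage before any execution; raises naming the offender."""
    if not isinstance(config, dict) or "stages" not in config:
        raise ValidationError("pipeline config must be a mapping with a 'stages' list")
    for i, stage in enumerate(config["stages"]):
        op = stage.get("operation")
        if op not in STAGE_REGISTRY:
            raise ValidationError(
                f"stage {i}: unknown operation {op!r}; expected one of {sorted(STAGE_REGISTRY)}"
            )
        try:
            STAGE_REGISTRY[op][0](stage.get("params", {}))
        except ValidationError as exc:
            raise ValidationError(f"stage {i} ({op}): {exc}") from exc


def run_pipeline(ws: Workspace, config: dict) -> dict:
    """Execute the stages in order; returns the machine-readable report.

    All stages are validated up front. The first failing stage aborts the run
    with :class:`PipelineError`; outputs of completed stages remain in the
    workspace and the report flags the failure.
    """
    validate_config(config)
    seed = int(config.get("seed", 0))
    report = {"seed": seed, "stages": []}
    for i, stage in enumerate(config["stages"]):
        op = stage["operation"]
        params = stage.get("params", {})
        entry = {"operation": op, "params": params}
        t0 = time.perf_counter()
        try:
            outputs = STAGE_REGISTRY[op][1](ws, params, seed)
        except Exception as exc:
            entry.update(status="failed", error=str(exc))
            report["stages"].append(entry)
            report["failed_stage"] = i
            _write_report(ws, report)
            raise PipelineError(f"stage {i} ({op}) failed: {exc}", report) from exc
        entry.update(status="ok", outputs=outputs, elapsed_s=round(time.perf_counter() - t0, 3))
        report["stages"].append(entry)
        ws.record_stage(op, params)
    ws.save_session()
    _write_report(ws, report)
    return report


def _write_report(ws: Workspace, report: dict) -> None:
    (ws.root_path / REPORT_FILE).write_text(json.dumps(report, indent=2))


def load_config(path) -> dict:
    """Read a YAML pipeline config."""
    try:
        doc = yaml.safe_load(open(path).read())
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"config {path} must be a YAML mapping")
    return doc


def replay_session(ws: Workspace, session: dict, seed: int = 0) -> dict:
    """Re-run a saved session's stages on a fresh workspace."""
    return run_pipeline(ws, {"seed": seed, "stages": session["stages"]})
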