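import numpy as np
import pytest

from volseg.errors import ValidationError
from volseg.label_splitter import (
    SplitRule,
    apply_rules,
    classes_to_volume,
    extract_objects,
    measure_objects,
    rules_from_json,
)


def _random_object_volume(rng, n_objects=3, shape=(24, 24, 24)):
    """Disjoint random axis-aligned boxes with random intensities."""
    seg = np.zeros(shape, dtype=np.int32)
    intensity = rng.random(shape)
    placed = 0
    while placed < n_objects:
        size = rng.integers(2, 6, size=3)
        pos = [rng.integers(0, shape[a] - size[a]) for a in range(3)]
        sl = tuple(slice(p, p + s) for p, s in zip(pos, size))
        pad = tuple(
            slice(max(0, p - 1), min(shape[a], p + s + 1))
            for a, (p, s) in enumerate(zip(pos, size))
        )
        if seg[pad].any():
            continue
        seg[sl] = 1
        placed += 1
    return seg, intensity


class TestExtractObjects:
    def test_two_disjoint_cubes(self):
        seg = np.zeros((10, 10, 10), dtype=np.int32)
        seg[1:3, 1:3, 1:3] = 1
        seg[6:8, 6:8, 6:8] = 1
        objects, ids = extract_objects(seg)
        assert len(ids) == 2
        assert set(np.unique(objects)) == {0, 1, 2}

    def test_diagonal_touch_connectivity(self):
        seg = np.zeros((4, 4, 4), dtype=np.int32)
        seg[0, 0, 0] = 1
        seg[1, 1, 1] = 1
        _, ids26 = extract_objects(seg, connectivity=26)
        _, ids6 = extract_objects(seg, connectivity=6)
        assert len(ids26) == 1
        assert len(ids6) == 2

    def test_empty_volume(self):
        _, ids = extract_objects(np.zeros((5, 5, 5), dtype=np.int32))
        assert len(ids) == 0

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            extract_objects(np.zeros((3, 3, 3)))

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValidationError):
            extract_objects(np.zeros((3, 3, 3), dtype=np.int32), connectivity=18)


class TestMeasureObjects:
    def test_cuboid_closed_form(self):
        seg = np.zeros((10, 10, 12), dtype=np.int32)
        seg[2:5, 3:7, 1:6] = 1  # 3 x 4 x 5 cuboid
        objects, _ = extract_objects(seg)
        row = measure_objects(objects, np.full(seg.shape, 0.7)).iloc[0]
        assert row.volume == 60
        assert (row.bbox_depth, row.bbox_height, row.bbox_width) == (3, 4, 5)
        assert row.bbox_volume == pytest.approx(60, abs=1e-9)
        assert row.log_bbox_volume == pytest.approx(np.log(60), abs=1e-9)
        assert row.mean_intensity == pytest.approx(0.7)
        assert row.sd_intensity == pytest.approx(0.0, abs=1e-12)
        # axis-aligned cuboid: principal axes = coordinate axes, extents sorted desc
        assert (row.obb_depth, row.obb_height, row.obb_width) == (5, 4, 3)
        assert row.obb_volume == pytest.approx(60, abs=1e-9)

    def test_single_voxel(self):
        seg = np.zeros((6, 6, 6), dtype=np.int32)
        seg[2, 3, 4] = 1
        objects, _ = extract_objects(seg)
        row = measure_objects(objects, np.full(seg.shape, 0.5)).iloc[0]
        assert (row.position_z, row.position_y, row.position_x) == (2, 3, 4)
        assert row.volume == 1
        assert (row.bbox_depth, row.bbox_height, row.bbox_width) == (1, 1, 1)
        assert (row.obb_depth, row.obb_height, row.obb_width) == (1, 1, 1)
        assert row.log_bbox_volume == 0.0

    def test_brute_force_oracle_on_random_objects(self, rng):
        """Per-voxel recomputation of every statistic for random small objects."""
        for trial in range(10):
            seg, intensity = _random_object_volume(rng)
            objects, ids = extract_objects(seg)
            table = measure_objects(objects, intensity)
            assert len(table) == len(ids)
            for _, row in table.iterrows():
                coords = np.argwhere(objects == row.object_id)
                vals = intensity[objects == row.object_id]
                assert row.volume == len(coords)
                assert row.mean_intensity == pytest.approx(vals.mean())
                assert row.var_intensity == pytest.approx(vals.var())
                assert row.sd_intensity == pytest.approx(vals.std())
                assert row.var_intensity == pytest.approx(row.sd_intensity**2)
                np.testing.assert_allclose(
                    [row.position_z, row.position_y, row.position_x], coords.mean(axis=0)
                )
                dims = coords.max(axis=0) - coords.min(axis=0) + 1
                assert [row.bbox_depth, row.bbox_height, row.bbox_width] == dims.tolist()
                assert row.bbox_volume == pytest.approx(np.prod(dims))
                # centroid inside bbox; volume <= bbox volume; logs consistent
                assert np.all(coords.min(axis=0) <= coords.mean(axis=0))
                assert np.all(coords.mean(axis=0) <= coords.max(axis=0))
                assert row.volume <= row.bbox_volume
                assert row.obb_volume > 0
                assert row.log_obb_volume == pytest.approx(np.log(row.obb_volume))

    def test_obb_matches_exhaustive_rotation_search(self, rng):
        """PCA-oriented box volume within 5% of a brute-force rotation scan."""
        from itertools import product

        from volseg.points import _euler_zyx

        for trial in range(3):
            seg, intensity = _random_object_volume(rng, n_objects=1)
            objects, _ = extract_objects(seg)
            row = measure_objects(objects, intensity).iloc[0]
            coords = np.argwhere(objects == 1).astype(float)
            coords -= coords.mean(axis=0)
            angles = np.linspace(0, np.pi / 2, 8)
            best = np.inf
            for az, ay, ax in product(angles, repeat=3):
                proj = coords @ _euler_zyx((az, ay, ax))
                ext = proj.max(axis=0) - proj.min(axis=0) + 1.0
                best = min(best, float(np.prod(ext)))
            assert row.obb_volume <= best * 1.05

    def test_conservation_of_foreground(self, rng):
        seg, intensity = _random_object_volume(rng, n_objects=4)
        objects, _ = extract_objects(seg)
        table = measure_objects(objects, intensity)
        assert table.volume.sum() == (seg != 0).sum()


class TestApplyRules:
    @pytest.fixture()
    def table(self, rng):
        seg = np.zeros((12, 12, 12), dtype=np.int32)
        seg[1:4, 1:5, 1:6] = 1  # volume 60
        seg[8:10, 8:10, 8:11] = 1  # volume 12
        intensity = np.full(seg.shape, 0.3)
        objects, _ = extract_objects(seg)
        return measure_objects(objects, intensity)

    def test_single_threshold_rule(self, table):
        rules = [SplitRule("volume", ">", 50, class_id=7)]
        cmap = apply_rules(table, rules, default_class=1)
        assert cmap == {1: 7, 2: 1}

    def test_later_rule_overrides(self, table):
        rules = [
            SplitRule("volume", ">", 50, class_id=7),
            SplitRule("mean_intensity", "<", 0.5, class_id=9),
        ]
        cmap = apply_rules(table, rules, default_class=1)
        assert cmap[1] == 9  # satisfied both; later rule wins

    def test_empty_rule_list_all_default(self, table):
        assert set(apply_rules(table, [], default_class=4).values()) == {4}

    def test_disjoint_rules_commute(self, table):
        a = [SplitRule("volume", ">", 50, 7), SplitRule("volume", "<", 20, 8)]
        assert apply_rules(table, a, 0) == apply_rules(table, a[::-1], 0)

    def test_unknown_feature_rejected(self, table):
        with pytest.raises(ValidationError):
            apply_rules(table, [SplitRule("girth", ">", 1, 2)], 0)

    def test_unknown_comparator_rejected(self):
        with pytest.raises(ValidationError):
            SplitRule("volume", "!=", 1, 2)

    def test_rules_from_json_roundtrip(self):
        items = [{"feature": "volume", "comparator": ">=", "threshold": 3, "class": 2}]
        rules = rules_from_json(items)
        assert rules[0] == SplitRule("volume", ">=", 3.0, 2)
        with pytest.raises(ValidationError):
            rules_from_json([{"feature": "volume"}])


class TestClassesToVolume:
    def test_all_to_one_class(self):
        seg = np.zeros((6, 6, 6), dtype=np.int32)
        seg[0, 0, 0] = 1
        seg[5, 5, 5] = 1
        objects, ids = extract_objects(seg)
        vol = classes_to_volume(objects, {int(i): 1 for i in ids})
        assert set(np.unique(vol)) == {0, 1}

    def test_identity_map_preserves_partition(self):
        seg = np.zeros((6, 6, 6), dtype=np.int32)
        seg[0:2, 0, 0] = 1
        seg[4:6, 5, 5] = 1
        objects, ids = extract_objects(seg)
        vol = classes_to_volume(objects, {int(i): int(i) for i in ids})
        assert np.array_equal(vol, objects)

    def test_missing_id_rejected(self):
        seg = np.zeros((4, 4, 4), dtype=np.int32)
        seg[0, 0, 0] = 1
        objects, _ = extract_objects(seg)
        with pytest.raises(ValidationError):
            classes_to_volume(objects, {})


def test_iterative_splitting_composes(rng):
    """Re-splitting the objects of one class never alters other classes."""
    seg, intensity = _random_object_volume(rng, n_objects=5)
    objects, _ = extract_objects(seg)
    table = measure_objects(objects, intensity)
    median_vol = float(table.volume.median())
    cmap = apply_rules(table, [SplitRule("volume", ">", median_vol, 2)], default_class=1)
    first = classes_to_volume(objects, cmap)
    # second splitter instance runs on class 1 only
    sub = np.where(first == 1, first, 0).astype(np.int32)
    sub_objects, sub_ids = extract_objects(sub)
    sub_table = measure_objects(sub_objects, intensity)
    sub_map = apply_rules(sub_table, [SplitRule("mean_intensity", ">", 0.5, 3)], default_class=1)
    second = classes_to_volume(sub_objects, sub_map)
    composed = np.where(first == 2, 2, second)
    assert np.array_equal(composed == 2, first == 2)
    assert np.all(np.isin(composed[first == 1], [1, 3]))
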