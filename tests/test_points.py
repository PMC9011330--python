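import numpy as np
import pytest

from volseg.errors import ValidationError
from volseg.points import (
    EllipsoidSpec,
    PointSet,
    acwe_refine,
    chan_vese_energy,
    rasterize_points,
    read_points_csv,
    write_points_csv,
)


def _lattice_sphere_count(radius):
    """Enumeration oracle: lattice offsets with dz^2+dy^2+dx^2 <= r^2."""
    r = int(np.ceil(radius))
    count = 0
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dz * dz + dy * dy + dx * dx <= radius * radius:
                    count += 1
    return count


class TestCSV:
    def test_read_three_rows(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("z,y,x,class\n1,2,3,1\n4.5,5,6,2\n7,8,9,1\n")
        ps = read_points_csv(p)
        assert len(ps) == 3
        assert ps.coords[1].tolist() == [4.5, 5.0, 6.0]
        assert ps.class_ids.tolist() == [1, 2, 1]

    def test_roundtrip_identity(self, tmp_path, rng):
        ps = PointSet(rng.random((5, 3)) * 50, rng.integers(1, 4, 5))
        path = tmp_path / "out.csv"
        write_points_csv(ps, path)
        back = read_points_csv(path)
        np.testing.assert_allclose(back.coords, ps.coords)
        assert np.array_equal(back.class_ids, ps.class_ids)

    def test_extra_columns_tolerated(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("name,z,y,x,score\nfoo,1,2,3,0.5\n")
        assert len(read_points_csv(p)) == 1

    def test_non_numeric_row_named_in_error(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("z,y,x\na,b,c\n")
        with pytest.raises(ValidationError, match="row 1"):
            read_points_csv(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("z,y\n1,2\n")
        with pytest.raises(ValidationError, match="x"):
            read_points_csv(p)


class TestRasterize:
    def test_half_voxel_radius_paints_one_voxel(self):
        ps = PointSet(np.array([[4.0, 4.0, 4.0]]))
        mask = rasterize_points(ps, EllipsoidSpec((0.5, 0.5, 0.5)), (9, 9, 9))
        assert mask.sum() == 1
        assert mask[4, 4, 4] == 1

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_sphere_counts_match_lattice_enumeration(self, radius):
        ps = PointSet(np.array([[10.0, 10.0, 10.0]]))
        mask = rasterize_points(ps, EllipsoidSpec((radius,) * 3), (21, 21, 21))
        assert (mask > 0).sum() == _lattice_sphere_count(radius)

    def test_radius_two_sphere_is_33_voxels(self):
        ps = PointSet(np.array([[4.0, 4.0, 4.0]]))
        mask = rasterize_points(ps, EllipsoidSpec((2, 2, 2)), (9, 9, 9))
        assert (mask > 0).sum() == 33

    def test_clipping_at_border(self):
        ps = PointSet(np.array([[0.0, 0.0, 0.0]]))
        mask = rasterize_points(ps, EllipsoidSpec((2, 2, 2)), (9, 9, 9))
        assert 0 < (mask > 0).sum() < 33

    def test_point_outside_volume_contributes_nothing(self):
        ps = PointSet(np.array([[50.0, 50.0, 50.0]]))
        mask = rasterize_points(ps, EllipsoidSpec((2, 2, 2)), (9, 9, 9))
        assert mask.sum() == 0

    def test_translation_equivariance(self):
        spec = EllipsoidSpec((2, 2, 2))
        a = rasterize_points(PointSet(np.array([[8.0, 8.0, 8.0]])), spec, (20, 20, 20))
        b = rasterize_points(PointSet(np.array([[11.0, 9.0, 10.0]])), spec, (20, 20, 20))
        assert np.array_equal(np.roll(a, (3, 1, 2), axis=(0, 1, 2)), b)

    def test_overlap_later_point_wins(self):
        ps = PointSet(np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 6.0]]), np.array([1, 2]))
        mask = rasterize_points(ps, EllipsoidSpec((2, 2, 2)), (11, 11, 11))
        assert mask[5, 5, 6] == 2
        assert mask[5, 5, 5] == 2  # overlapping center voxel taken by later point
        assert mask[5, 5, 3] == 1

    def test_rotated_ellipsoid_aligns_with_axis(self):
        # a prolate ellipsoid rotated 90 deg about z swaps its y/x extents
        spec0 = EllipsoidSpec((1.0, 4.0, 1.0))
        spec90 = EllipsoidSpec((1.0, 4.0, 1.0), orientation=(np.pi / 2, 0.0, 0.0))
        c = PointSet(np.array([[10.0, 10.0, 10.0]]))
        a = rasterize_points(c, spec0, (21, 21, 21))
        b = rasterize_points(c, spec90, (21, 21, 21))
        assert a.sum() == b.sum()
        assert np.array_equal(a.transpose(0, 2, 1), b)

    def test_class_ids_painted(self):
        ps = PointSet(np.array([[3.0, 3.0, 3.0]]), np.array([5]))
        mask = rasterize_points(ps, EllipsoidSpec((1, 1, 1)), (7, 7, 7))
        assert set(np.unique(mask)) == {0, 5}


class TestACWE:
    @staticmethod
    def _sphere(shape, center, radius):
        zz, yy, xx = np.indices(shape)
        return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2

    @staticmethod
    def _dice(a, b):
        return 2 * (a & b).sum() / (a.sum() + b.sum())

    def test_zero_iterations_is_identity(self):
        mask = self._sphere((12, 12, 12), (6, 6, 6), 3)
        img = np.full((12, 12, 12), 0.5)
        out = acwe_refine(mask, img, iters=0)
        assert np.array_equal(out.astype(bool), mask)

    def test_expands_to_brighter_true_sphere(self):
        shape = (20, 20, 20)
        true = self._sphere(shape, (10, 10, 10), 6)
        img = np.where(true, 0.6, 0.2)
        seed = self._sphere(shape, (10, 10, 10), 3)
        refined = acwe_refine(seed, img, iters=30).astype(bool)
        assert self._dice(refined, true) > self._dice(seed, true)

    def test_contracts_onto_smaller_true_sphere(self):
        shape = (20, 20, 20)
        true = self._sphere(shape, (10, 10, 10), 3)
        img = np.where(true, 0.6, 0.2)
        seed = self._sphere(shape, (10, 10, 10), 6)
        refined = acwe_refine(seed, img, iters=30).astype(bool)
        assert refined.sum() < seed.sum()
        assert self._dice(refined, true) > self._dice(seed, true)

    def test_energy_non_increasing_on_noise_free_phantom(self):
        shape = (20, 20, 20)
        true = self._sphere(shape, (10, 10, 10), 6)
        img = np.where(true, 0.6, 0.2)
        seed = self._sphere(shape, (10, 10, 10), 3)
        energies = [
            chan_vese_energy(acwe_refine(seed, img, iters=k).astype(bool), img)
            for k in range(6)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_deterministic(self, rng):
        img = rng.random((10, 10, 10))
        seed = self._sphere((10, 10, 10), (5, 5, 5), 3)
        a = acwe_refine(seed, img, iters=10)
        b = acwe_refine(seed, img, iters=10)
        assert np.array_equal(a, b)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            acwe_refine(np.zeros((5, 5, 5), bool), np.zeros((5, 5, 5)), iters=1)


class TestPointSetValidation:
    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            PointSet(np.array([[np.nan, 0, 0]]))

    def test_bad_shape_rejected(self):
        with pytest.raises(ValidationError):
            PointSet(np.zeros((3, 2)))

    def test_bad_radii_rejected(self):
        with pytest.raises(ValidationError):
            EllipsoidSpec((0.0, 1.0, 1.0))
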