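import numpy as np
import pytest

from volseg import synthetic
from volseg.errors import ValidationError
from volseg.multiaxis import (
    ThresholdPredictor2D,
    augment_pair,
    make_training_pairs,
    predict_fuse,
    restack,
    select_winners,
    slice_stacks,
    train_predictor_2d,
    votes_per_voxel,
)


class ConstantPredictor:
    """Always votes one class with full confidence."""

    def __init__(self, cls, n_classes=3):
        self.cls = cls
        self.n_classes = n_classes

    def predict(self, image):
        s = np.zeros((self.n_classes,) + image.shape)
        s[self.cls] = 1.0
        return s


class BadShapePredictor:
    n_classes = 2

    def predict(self, image):
        return np.zeros((2, 3, 3))


class TestSlicing:
    def test_counts_sum_of_dimensions(self):
        stacks, plan = slice_stacks(np.zeros((4, 5, 6)))
        assert [len(s) for s in stacks] == [4, 5, 6]
        assert plan.total == 15

    def test_restack_roundtrip(self, rng):
        vol = rng.random((7, 8, 9))
        stacks, _ = slice_stacks(vol)
        for axis in range(3):
            assert np.array_equal(restack(stacks[axis], axis), vol)

    def test_non_3d_rejected(self):
        with pytest.raises(ValidationError):
            slice_stacks(np.zeros((4, 4)))


class TestTrainingPairs:
    def test_counts_and_alignment(self, rng):
        vol = rng.random((4, 4, 4))
        labels = (vol > 0.5).astype(np.int32)
        pairs = make_training_pairs(vol, labels)
        assert len(pairs) == 12
        for img, mask in pairs:
            assert img.shape == mask.shape
            assert np.array_equal(mask, (img > 0.5).astype(np.int32))

    def test_constant_label_volume_gives_constant_masks(self, rng):
        pairs = make_training_pairs(rng.random((4, 4, 4)), np.full((4, 4, 4), 2, dtype=np.int32))
        assert all(np.all(mask == 2) for _, mask in pairs)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            make_training_pairs(np.zeros((4, 4, 4)), np.zeros((4, 4, 5), dtype=np.int32))


class TestAugment:
    @pytest.fixture()
    def pair(self, rng):
        img = rng.random((10, 12))
        mask = (img > 0.5).astype(np.int32)
        return img, mask

    @pytest.mark.parametrize("op", ["flip_h", "flip_v"])
    def test_flip_is_involution(self, pair, op):
        once = augment_pair(pair, [op], seed=0)
        twice = augment_pair(once, [op], seed=0)
        assert np.allclose(twice[0], pair[0])
        assert np.array_equal(twice[1], pair[1])

    def test_contrast_leaves_mask_untouched(self, pair):
        img, mask = augment_pair(pair, ["contrast"], seed=3)
        assert np.array_equal(mask, pair[1])
        assert not np.allclose(img, pair[0])

    def test_deterministic_per_seed(self, pair):
        a = augment_pair(pair, ["elastic", "contrast"], seed=5)
        b = augment_pair(pair, ["elastic", "contrast"], seed=5)
        assert np.allclose(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_elastic_moves_image_and_mask_together(self):
        # mask is a deterministic function of the image, so a shared geometric
        # transform keeps them consistent away from interpolated edges
        img = np.zeros((16, 16))
        img[4:12, 4:12] = 1.0
        mask = img.astype(np.int32)
        wimg, wmask = augment_pair((img, mask), ["elastic"], seed=2)
        strict = (wimg > 0.99) & (wmask == 0)
        assert strict.mean() < 0.02

    def test_unknown_op_rejected(self, pair):
        with pytest.raises(ValidationError):
            augment_pair(pair, ["rotate45"], seed=0)


class TestFusion:
    def test_oracle_predictor_recovers_ground_truth(self):
        spec = synthetic.PhantomSpec(shape=(20, 24, 28), n_objects=2, noise_sigma=0.0,
                                     seed=3, radius_range=(3, 5))
        volume, truth, _ = synthetic.generate_phantom(spec)
        fused = predict_fuse(ThresholdPredictor2D(0.5), volume, rotations=(90, 180, 270))
        assert np.array_equal(fused, (truth > 0).astype(fused.dtype))

    def test_constant_predictor_gives_constant_volume(self, rng):
        fused = predict_fuse(ConstantPredictor(2), rng.random((5, 6, 7)))
        assert np.all(fused == 2)

    def test_vote_tally_invariant(self, rng):
        vol = rng.random((4, 4, 4))
        _, votes, _ = predict_fuse(ThresholdPredictor2D(), vol, rotations=(90,), return_tally=True)
        assert np.all(votes.sum(axis=0) == votes_per_voxel((90,)))
        assert votes_per_voxel((90,)) == 6

    def test_rotation_consistency_for_equivariant_predictor(self, rng):
        vol = rng.random((6, 6, 6))
        base = predict_fuse(ThresholdPredictor2D(), vol)
        with_rot = predict_fuse(ThresholdPredictor2D(), vol, rotations=(90, 180, 270))
        assert np.array_equal(base, with_rot)

    def test_deterministic(self, rng):
        vol = rng.random((5, 5, 5))
        assert np.array_equal(
            predict_fuse(ThresholdPredictor2D(), vol), predict_fuse(ThresholdPredictor2D(), vol)
        )

    def test_bad_predictor_shape_rejected(self, rng):
        with pytest.raises(ValidationError):
            predict_fuse(BadShapePredictor(), rng.random((4, 4, 4)))

    def test_invalid_rotation_rejected(self, rng):
        with pytest.raises(ValidationError):
            predict_fuse(ThresholdPredictor2D(), rng.random((4, 4, 4)), rotations=(45,))


class TestWinnerSelection:
    def _brute_force(self, votes, scores):
        """Per-voxel enumeration: max votes, then max score, then smallest id."""
        n_classes = votes.shape[0]
        flat_v = votes.reshape(n_classes, -1)
        flat_s = scores.reshape(n_classes, -1)
        out = np.empty(flat_v.shape[1], dtype=int)
        for i in range(flat_v.shape[1]):
            best = 0
            for c in range(1, n_classes):
                if flat_v[c, i] > flat_v[best, i] or (
                    flat_v[c, i] == flat_v[best, i] and flat_s[c, i] > flat_s[best, i]
                ):
                    best = c
            out[i] = best
        return out.reshape(votes.shape[1:])

    def test_matches_brute_force_on_random_tallies(self, rng):
        votes = rng.integers(0, 4, size=(4, 1000))
        scores = np.round(rng.random((4, 1000)), 2)  # rounding forces score ties too
        assert np.array_equal(select_winners(votes, scores), self._brute_force(votes, scores))

    def test_permutation_invariance_of_vote_order(self, rng):
        # accumulated tallies are order-free by construction; summing votes in
        # any order gives the same totals, hence the same winners
        parts = [rng.integers(0, 2, size=(3, 50)) for _ in range(5)]
        scores = rng.random((3, 50))
        total = sum(parts)
        perm_total = sum(parts[::-1])
        assert np.array_equal(select_winners(total, scores), select_winners(perm_total, scores))


class TestTrainablePredictor:
    @staticmethod
    def disk_pair(seed):
        r = np.random.default_rng(seed)
        yy, xx = np.mgrid[:32, :32]
        cy, cx, rad = r.uniform(8, 24), r.uniform(8, 24), r.uniform(4, 8)
        mask = ((yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2).astype(np.int32)
        img = np.where(mask, 0.8, 0.2) + r.normal(0, 0.1, (32, 32))
        return img, mask

    def test_toy_heldout_accuracy(self):
        train = [self.disk_pair(i) for i in range(20)]
        test = [self.disk_pair(100 + i) for i in range(5)]
        predictor = train_predictor_2d(train, seed=0)
        accs = [
            (np.argmax(predictor.predict(img), axis=0) == mask).mean() for img, mask in test
        ]
        assert np.mean(accs) > 0.9

    def test_reproducible_per_seed(self):
        train = [self.disk_pair(i) for i in range(4)]
        img, _ = self.disk_pair(50)
        a = train_predictor_2d(train, seed=3).predict(img)
        b = train_predictor_2d(train, seed=3).predict(img)
        assert np.allclose(a, b)

    def test_empty_training_list_rejected(self):
        with pytest.raises(ValidationError):
            train_predictor_2d([], seed=0)
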