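"""Augmentation regimes and patient-level splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radulna.core import DRRImage, PairingError, ParameterError
from radulna.augment import (
    augment_2d_pairs,
    augment_3d,
    centered_matrix,
    make_split,
    warp_image_matrix,
    warp_pair,
)
from radulna.drr import ProjectionGeometry
from radulna.frames import build_frame, normalize_volume
from radulna.phantoms import PhantomSpec, rasterize_phantom
from radulna.transforms import (
    Affine2D,
    RigidTransform3D,
    sample_affine2d,
    sample_rigid_transforms,
)


@pytest.fixture(scope="module")
def tiny_sample():
    """A coarsely normalized phantom for cheap augmentation runs."""
    spec = PhantomSpec()
    ct, label, lm = rasterize_phantom(spec, (36, 36, 48), 2.5)
    return normalize_volume(ct, label, build_frame(lm), spacing=5.0)


@pytest.fixture(scope="module")
def tiny_geom():
    return ProjectionGeometry(detector_shape=(16, 16), pixel_spacing=5.0,
                              step_length=2.5)


class TestRigidSampling:
    def test_draws_stay_in_stated_ranges(self):
        tfs = sample_rigid_transforms(1000, 30.0, 30.0, seed=4)
        rots = np.array([t.rotation for t in tfs])
        trans = np.array([t.translation for t in tfs])
        assert rots.min() >= -30 and rots.max() <= 30
        assert trans.min() >= -30 and trans.max() <= 30
        # uniform draws should roam most of the range
        assert rots.max() > 25 and rots.min() < -25

    def test_identity_matrix_at_zero(self):
        np.testing.assert_allclose(RigidTransform3D().matrix, np.eye(4))

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_inverse_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        tf = RigidTransform3D(rotation=rng.uniform(-180, 180, 3),
                              translation=rng.uniform(-50, 50, 3))
        pts = rng.normal(0, 30, (10, 3))
        np.testing.assert_allclose(
            tf.inverse_apply_points(tf.apply_points(pts)), pts, atol=1e-9
        )


class TestAugment3D:
    def test_count_conservation(self, tiny_sample, tiny_geom):
        items = augment_3d(tiny_sample, tiny_geom, factor=7, seed=0)
        assert len(items) == 7

    def test_zero_ranges_reproduce_unaugmented_drr(self, tiny_sample, tiny_geom):
        from radulna.drr import render_bone_drr

        items = augment_3d(tiny_sample, tiny_geom, factor=3,
                           rotation_range_deg=0.0, translation_range_mm=0.0,
                           seed=1)
        plain = render_bone_drr(tiny_sample.ct, tiny_sample.label, tiny_geom)
        for tf, drr, label in items:
            np.testing.assert_allclose(tf.as_params(), np.zeros(6))
            np.testing.assert_allclose(drr.pixels, plain.pixels, atol=1e-9)
            assert label is tiny_sample.label

    def test_seeded_determinism(self, tiny_sample, tiny_geom):
        a = augment_3d(tiny_sample, tiny_geom, factor=4, seed=9)
        b = augment_3d(tiny_sample, tiny_geom, factor=4, seed=9)
        for (ta, da, _), (tb, db, _) in zip(a, b):
            np.testing.assert_array_equal(ta.as_params(), tb.as_params())
            np.testing.assert_array_equal(da.pixels, db.pixels)

    def test_factor_below_one_rejected(self, tiny_sample, tiny_geom):
        with pytest.raises(ParameterError):
            augment_3d(tiny_sample, tiny_geom, factor=0)


def random_pair(seed, shape=(32, 32)):
    """Smooth seeded test images (band-limited, like real DRRs)."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    blob = np.zeros(shape)
    blob[8:24, 10:20] = rng.uniform(0.5, 1.0, (16, 10))
    blob = gaussian_filter(blob, 2.0)
    noisy = gaussian_filter(blob + rng.uniform(0, 0.1, shape), 1.0)
    return (
        DRRImage(pixels=noisy, pixel_spacing=1.0),
        DRRImage(pixels=blob, pixel_spacing=1.0),
    )


class TestAugment2D:
    def test_count_conservation(self):
        pairs = [random_pair(s) for s in range(5)]
        out = augment_2d_pairs(pairs, factor=13, seed=0)
        assert len(out) == 5 * 13

    def test_identity_ranges_reproduce_inputs(self):
        pairs = [random_pair(3)]
        out = augment_2d_pairs(pairs, factor=2, translation_range_mm=0.0,
                               rotation_range_deg=0.0, scale_range=(1.0, 1.0),
                               shear_range_deg=0.0, seed=0)
        for xr, dr in out:
            np.testing.assert_allclose(xr.pixels, pairs[0][0].pixels, atol=1e-9)
            np.testing.assert_allclose(dr.pixels, pairs[0][1].pixels, atol=1e-9)

    def test_same_affine_applied_to_both_members(self):
        pairs = [(random_pair(1)[0], random_pair(1)[0])]  # identical members
        out = augment_2d_pairs(pairs, factor=5, seed=2)
        for xr, dr in out:
            np.testing.assert_array_equal(xr.pixels, dr.pixels)

    def test_inverse_affine_round_trip(self):
        xray, drr = random_pair(7)
        aff = Affine2D(translation=[3.0, -2.0], rotation=8.0,
                       scale=[1.05, 0.95], shear=3.0)
        G = centered_matrix(aff, xray.pixels.shape, xray.pixel_spacing)
        warped = warp_image_matrix(xray, G)
        restored = warp_image_matrix(warped, np.linalg.inv(G))
        dyn = xray.pixels.max() - xray.pixels.min()
        interior = np.s_[4:-4, 4:-4]
        rms = np.sqrt(np.mean((restored.pixels[interior] -
                               xray.pixels[interior]) ** 2))
        assert rms < 0.02 * dyn

    def test_shape_mismatch_rejected(self):
        a = DRRImage(pixels=np.zeros((16, 16)), pixel_spacing=1.0)
        b = DRRImage(pixels=np.zeros((16, 18)), pixel_spacing=1.0)
        with pytest.raises(PairingError):
            warp_pair(a, b, Affine2D())

    def test_affine_draws_within_ranges(self):
        affs = sample_affine2d(500, 10.0, 10.0, (0.9, 1.1), 5.0, seed=6)
        assert all(abs(a.rotation) <= 10 for a in affs)
        assert all(np.all(np.abs(a.translation) <= 10) for a in affs)
        assert all(np.all((a.scale >= 0.9) & (a.scale <= 1.1)) for a in affs)
        assert all(abs(a.shear) <= 5 for a in affs)


class TestSplit:
    def test_eight_patients_four_folds(self):
        plan = make_split(list("abcdefgh"), folds=4, seed=0)
        assert all(len(f) == 2 for f in plan.test_folds)

    def test_folds_disjoint_and_exhaustive(self):
        ids = [f"p{i}" for i in range(13)]
        plan = make_split(ids, folds=4, seed=3)
        seen = [p for fold in plan.test_folds for p in fold]
        assert sorted(seen) == sorted(ids)

    def test_no_patient_in_both_train_and_validation(self):
        ids = [f"p{i}" for i in range(20)]
        plan = make_split(ids, folds=4, val_frac=0.15, seed=1)
        for k in range(4):
            train = set(plan.train_patients[k])
            val = set(plan.val_patients[k])
            test = set(plan.test_folds[k])
            assert not train & val
            assert not (train | val) & test
            assert sorted(train | val | test) == sorted(ids)

    def test_determinism(self):
        ids = [f"p{i}" for i in range(9)]
        assert make_split(ids, seed=5).test_folds == make_split(ids, seed=5).test_folds

    def test_too_few_patients_rejected(self):
        with pytest.raises(ParameterError):
            make_split(["a", "b"], folds=4)
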