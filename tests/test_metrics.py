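"""Evaluation metrics: MAE, marching-cubes surfaces, ASD (against a brute-
force oracle), histogram matching, experiment reports."""

import numpy as np
import pytest

from radulna.core import DegenerateInputError, DRRImage, LabelVolume, ParameterError
from radulna.metrics import (
    SurfacePointCloud,
    asd,
    histogram_match_baseline,
    mae,
    run_experiment,
    surface_from_label,
)


def brute_force_asd(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive double-loop evaluation of the symmetric surface distance."""
    d_ab = [min(np.linalg.norm(p - q) for q in b) for p in a]
    d_ba = [min(np.linalg.norm(p - q) for p in a) for q in b]
    return (sum(d_ab) + sum(d_ba)) / (len(a) + len(b))


def make_label(mask, spacing=1.0, origin=None):
    mask = np.asarray(mask)
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if origin is None:
        origin = -sp * (np.asarray(mask.shape) - 1) / 2.0
    return LabelVolume(voxels=mask.astype(np.uint8), spacing=sp, origin=origin)


class TestMAE:
    def test_identical_images_zero(self):
        img = DRRImage(pixels=np.random.default_rng(0).random((8, 8)),
                       pixel_spacing=1.0)
        assert mae(img, img) == 0.0

    def test_constant_offset(self):
        a = DRRImage(pixels=np.zeros((2, 2)), pixel_spacing=1.0)
        b = DRRImage(pixels=np.ones((2, 2)), pixel_spacing=1.0)
        assert mae(a, b) == 1.0

    def test_hand_arithmetic(self):
        a = np.array([[0.0, 0.2], [0.4, 0.6]])
        b = np.array([[0.1, 0.1], [0.1, 0.1]])
        assert mae(a, b) == pytest.approx(0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            mae(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSurface:
    def test_single_voxel_closed_surface(self):
        mask = np.zeros((9, 9, 9))
        mask[4, 4, 4] = 1
        label = make_label(mask)
        cloud = surface_from_label(label, 1)
        centroid = cloud.points.mean(axis=0)
        np.testing.assert_allclose(centroid, [0, 0, 0], atol=0.5)

    def test_points_within_volume_bounds(self, ref_phantom):
        _, label, _ = ref_phantom
        cloud = surface_from_label(label, 1)
        lo = label.origin - label.spacing
        hi = label.origin + label.spacing * np.asarray(label.shape)
        assert (cloud.points >= lo).all() and (cloud.points <= hi).all()
        assert np.all(np.isfinite(cloud.points))

    def test_sphere_surface_radius(self):
        n, sp, r = 31, 1.0, 10.0
        xs = (np.arange(n) - (n - 1) / 2) * sp
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        mask = X**2 + Y**2 + Z**2 <= r * r
        cloud = surface_from_label(make_label(mask, sp), 1)
        dist = np.linalg.norm(cloud.points, axis=1)
        assert np.all(np.abs(dist - r) <= sp)

    def test_empty_class_rejected(self):
        with pytest.raises(DegenerateInputError, match="empty"):
            surface_from_label(make_label(np.zeros((4, 4, 4))), 1)


class TestASD:
    def random_cloud(self, seed, n=200):
        rng = np.random.default_rng(seed)
        return rng.normal(0, 10, (n, 3))

    def test_self_distance_zero(self):
        cloud = SurfacePointCloud(self.random_cloud(0))
        assert asd(cloud, cloud) == 0.0

    def test_symmetry(self):
        a = SurfacePointCloud(self.random_cloud(1))
        b = SurfacePointCloud(self.random_cloud(2))
        assert abs(asd(a, b) - asd(b, a)) < 1e-12

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force_oracle(self, seed):
        a = self.random_cloud(seed)
        b = self.random_cloud(seed + 100)
        fast = asd(SurfacePointCloud(a), SurfacePointCloud(b))
        assert fast == pytest.approx(brute_force_asd(a, b), abs=1e-9)

    def test_rigid_motion_equivariance(self):
        from radulna.transforms import RigidTransform3D

        a = self.random_cloud(7)
        b = self.random_cloud(8)
        base = asd(SurfacePointCloud(a), SurfacePointCloud(b))
        tf = RigidTransform3D(rotation=[30, -50, 75], translation=[5, -8, 11])
        moved = asd(
            SurfacePointCloud(tf.apply_points(a)),
            SurfacePointCloud(tf.apply_points(b)),
        )
        assert moved == pytest.approx(base, abs=1e-9)

    def test_translated_cube_approaches_closed_form(self):
        """Surface clouds of a cube and its translate: ASD from the point
        clouds must match the exhaustive oracle exactly, and converge with
        density toward a stable value."""
        vals = []
        for n in (6, 12, 24):
            xs = np.linspace(0, 10, n)
            face = np.array(
                [[a, b, c] for a in xs for b in xs for c in (0.0, 10.0)]
            )
            cube = np.vstack([face, face[:, [0, 2, 1]], face[:, [2, 0, 1]]])
            shifted = cube + np.array([1.0, 0, 0])
            fast = asd(SurfacePointCloud(cube), SurfacePointCloud(shifted))
            if n <= 12:
                assert fast == pytest.approx(
                    brute_force_asd(cube, shifted), abs=1e-9
                )
            vals.append(fast)
        assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0]) + 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            SurfacePointCloud(np.zeros((2, 3)))


class TestHistogramMatch:
    def test_template_equal_image_is_identity(self):
        rng = np.random.default_rng(0)
        img = DRRImage(pixels=rng.uniform(0, 1, (64, 64)), pixel_spacing=1.0)
        out = histogram_match_baseline(img, img, np.ones((64, 64), dtype=bool))
        np.testing.assert_allclose(out.pixels, img.pixels, atol=0.02)

    def test_masked_cdf_agreement(self):
        rng = np.random.default_rng(1)
        img = DRRImage(pixels=rng.normal(0.5, 0.2, (64, 64)), pixel_spacing=1.0)
        tmpl = DRRImage(pixels=rng.gamma(2.0, 0.1, (64, 64)), pixel_spacing=1.0)
        mask = np.zeros((64, 64), dtype=bool)
        mask[8:56, 8:56] = True
        out = histogram_match_baseline(img, tmpl, mask)
        from scipy.stats import ks_2samp

        stat = ks_2samp(out.pixels[mask], tmpl.pixels[mask]).statistic
        assert stat < 0.05

    def test_outside_mask_exactly_zero(self):
        rng = np.random.default_rng(2)
        img = DRRImage(pixels=rng.uniform(0.2, 1, (32, 32)), pixel_spacing=1.0)
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:20, 10:20] = True
        out = histogram_match_baseline(img, img, mask)
        assert (out.pixels[~mask] == 0).all()

    def test_empty_mask_rejected(self):
        img = DRRImage(pixels=np.ones((8, 8)), pixel_spacing=1.0)
        with pytest.raises(DegenerateInputError):
            histogram_match_baseline(img, img, np.zeros((8, 8), dtype=bool))


class TestRunExperiment:
    def make_case(self, case_id, seed=0):
        rng = np.random.default_rng(seed)
        mask = np.zeros((12, 12, 12), dtype=np.uint8)
        mask[3:9, 3:9, 2:10] = 1
        mask[9:11, 3:9, 2:10] = 2
        truth = make_label(mask)
        img = DRRImage(pixels=rng.random((8, 8)), pixel_spacing=1.0)
        return {
            "case_id": case_id,
            "truth": truth,
            "reference": img,
            "images": {"ct_drr": img},
        }

    @staticmethod
    def fake_reconstruct(img):
        mask = np.zeros((12, 12, 12), dtype=np.uint8)
        mask[3:9, 3:9, 3:9] = 1
        mask[9:11, 3:9, 3:9] = 2
        return make_label(mask)

    def test_single_case_single_condition_has_two_rows(self):
        report = run_experiment([self.make_case("c0")], self.fake_reconstruct)
        assert len(report.rows) == 2
        assert set(report.rows.bone) == {"radius", "ulna"}

    def test_aggregates_recomputable_from_rows(self):
        cases = [self.make_case(f"c{i}", seed=i) for i in range(3)]
        report = run_experiment(cases, self.fake_reconstruct)
        agg = report.aggregates()
        for _, row in agg.iterrows():
            sel = report.rows[
                (report.rows.condition == row.condition)
                & (report.rows.bone == row.bone)
            ]["asd_mm"]
            assert row.asd_mean_mm == pytest.approx(sel.mean(), abs=1e-9)

    def test_missing_condition_rejected(self):
        cases = [self.make_case("a"), self.make_case("b")]
        cases[1]["images"] = {}
        with pytest.raises(ParameterError, match="missing"):
            run_experiment(cases, self.fake_reconstruct)
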