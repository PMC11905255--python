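"""Response matrix, forward model, scatter and calibration tests."""

import numpy as np
import pytest
from conftest import three_cameras

import scintidose as sd
from scintidose.optics import margin_mask


@pytest.fixture
def grid5():
    return sd.make_grid((5, 5, 5), 2.0)


def random_dose(grid, rng):
    return sd.DoseVolume(grid, rng.random(grid.shape))


class TestBuildResponseMatrix:
    def test_shadow_projection_each_axis(self, rng):
        """With lambda=0 and pixel pitch = voxel size, each camera sees the
        straight sum of the dose along its view axis."""
        g = sd.make_grid((8, 8, 8), 2.0)
        cams = three_cameras(8, 2.0, lam=0.0)
        A = sd.build_response_matrix(g, cams)
        D = random_dose(g, rng)
        proj = sd.forward_project(A, D)
        assert np.allclose(proj.images["cam_top"], D.values.sum(axis=2))
        assert np.allclose(proj.images["cam_front"], D.values.sum(axis=1))
        assert np.allclose(proj.images["cam_side"], D.values.sum(axis=0))

    def test_point_source_unit_response(self):
        g = sd.make_grid((7, 7, 7), 2.0)
        cams = three_cameras(7, 2.0, lam=0.0)
        A = sd.build_response_matrix(g, cams)
        vals = np.zeros(g.shape)
        vals[3, 2, 4] = 1.0
        proj = sd.forward_project(A, sd.DoseVolume(g, vals))
        for img in proj.images.values():
            assert np.isclose(img.sum(), 1.0)
            assert (img > 0).sum() == 1

    def test_single_voxel_attenuation_closed_form(self):
        """A unit voxel at depth d from the exit face responds exp(-lambda*d)."""
        lam = 0.13
        g = sd.make_grid((5, 5, 5), 2.0)
        cam = sd.CameraModel(id="top", view_axis="+z", pixel_shape=(5, 5),
                             pixel_pitch=2.0, attenuation_lambda=lam)
        A = sd.build_response_matrix(g, [cam])
        vals = np.zeros(g.shape)
        k = 1
        vals[2, 2, k] = 1.0
        proj = sd.forward_project(A, sd.DoseVolume(g, vals))
        # voxel center at z = -4 + 2*k; exit face at z = +5
        depth = 5.0 - (-4.0 + 2.0 * k)
        assert np.isclose(proj.images["top"].max(), np.exp(-lam * depth), rtol=1e-12)

    def test_dense_product_oracle(self, grid5, rng):
        cams = three_cameras(5, 2.0, lam=0.05)
        A = sd.build_response_matrix(grid5, cams)
        D = random_dose(grid5, rng)
        dense = A.matrix.toarray()
        expected = dense @ D.ravel()
        got = sd.forward_project(A, D).vector
        assert np.allclose(got, expected, rtol=1e-12)

    def test_duplicate_axes_rejected(self, grid5):
        cams = [sd.CameraModel(id="a", view_axis="+z"),
                sd.CameraModel(id="b", view_axis="+z")]
        with pytest.raises(ValueError, match="duplicate"):
            sd.build_response_matrix(grid5, cams)

    def test_entries_bounded_and_nonnegative(self, grid5):
        cams = three_cameras(5, 2.0, lam=0.2)
        A = sd.build_response_matrix(grid5, cams)
        assert A.matrix.data.min() >= 0
        assert A.matrix.data.max() <= 1.0 + 1e-12

    def test_flux_conservation_lambda_zero(self, rng):
        """With no optical attenuation every camera collects the total dose."""
        g = sd.make_grid((6, 6, 6), 2.0)
        cams = three_cameras(10, 2.0, lam=0.0)  # sensor larger than phantom
        A = sd.build_response_matrix(g, cams)
        D = random_dose(g, rng)
        proj = sd.forward_project(A, D)
        for img in proj.images.values():
            assert np.isclose(img.sum(), D.total, rtol=1e-9)

    def test_monotonicity_in_dose(self, grid5, rng):
        cams = three_cameras(5, 2.0, lam=0.1)
        A = sd.build_response_matrix(grid5, cams)
        D = random_dose(grid5, rng)
        p0 = sd.forward_project(A, D, scatter_fraction=0.1).vector
        bumped = D.values.copy()
        bumped[2, 2, 2] += 1.0
        p1 = sd.forward_project(A, sd.DoseVolume(grid5, bumped), 0.1).vector
        assert np.all(p1 >= p0 - 1e-15)

    def test_pinhole_point_source_projects_near_center(self):
        g = sd.make_grid((9, 9, 9), 2.0)
        cam = sd.CameraModel(id="ph", view_axis="+z", pixel_shape=(15, 15),
                             pixel_pitch=2.0, projection_mode="pinhole",
                             focal_length=100.0)
        A = sd.build_response_matrix(g, [cam])
        vals = np.zeros(g.shape)
        vals[4, 4, 4] = 1.0  # voxel on the optical axis at the isocenter
        proj = sd.forward_project(A, sd.DoseVolume(g, vals))
        img = proj.images["ph"]
        assert np.isclose(img.sum(), 1.0)
        r, c = np.unravel_index(img.argmax(), img.shape)
        assert (r, c) == (7, 7)


class TestScatter:
    def test_forward_scatter_term(self, grid5, rng):
        cams = three_cameras(5, 2.0)
        A = sd.build_response_matrix(grid5, cams)
        D = random_dose(grid5, rng)
        s = 0.37
        p0 = sd.forward_project(A, D, 0.0).vector
        p1 = sd.forward_project(A, D, s).vector
        assert np.allclose(p1 - p0, s * D.total / A.n)

    def test_zero_dose_zero_projection(self, grid5):
        cams = three_cameras(5, 2.0)
        A = sd.build_response_matrix(grid5, cams)
        p = sd.forward_project(A, sd.DoseVolume(grid5, np.zeros(grid5.shape)), 1.0)
        assert np.all(p.vector == 0)

    def test_known_constant_background_recovered(self, rng):
        g = sd.make_grid((6, 6, 6), 2.0)
        cams = three_cameras(10, 2.0)  # margin pixels exist
        A = sd.build_response_matrix(g, cams)
        D = random_dose(g, rng)
        proj = sd.forward_project(A, D, 0.0)
        b = 0.123
        shifted = proj.with_images({k: v + b for k, v in proj.images.items()})
        cleaned, est = sd.estimate_and_remove_scatter(shifted, response=A)
        for cam_id in est:
            assert np.isclose(est[cam_id], b)
        assert np.allclose(cleaned.vector, proj.vector, atol=1e-12)

    def test_zero_background_is_identity(self, rng):
        g = sd.make_grid((6, 6, 6), 2.0)
        cams = three_cameras(10, 2.0)
        A = sd.build_response_matrix(g, cams)
        proj = sd.forward_project(A, random_dose(g, rng), 0.0)
        cleaned, est = sd.estimate_and_remove_scatter(proj, response=A)
        assert all(v == 0 for v in est.values())
        assert np.array_equal(cleaned.vector, proj.vector)

    def test_scatter_removal_matches_scatter_free_projection(self, rng):
        g = sd.make_grid((6, 6, 6), 2.0)
        cams = three_cameras(10, 2.0)
        A = sd.build_response_matrix(g, cams)
        D = random_dose(g, rng)
        clean_truth = sd.forward_project(A, D, 0.0).vector
        noisy = sd.forward_project(A, D, 0.2)
        cleaned, _ = sd.estimate_and_remove_scatter(noisy, response=A)
        rms = np.sqrt(((cleaned.vector - clean_truth) ** 2).mean())
        assert rms < 0.01 * max(clean_truth.max(), 1e-12)

    def test_no_margin_and_no_background_errors(self, grid5, rng):
        cams = three_cameras(5, 2.0)  # sensor exactly covers phantom
        A = sd.build_response_matrix(grid5, cams)
        proj = sd.forward_project(A, random_dose(grid5, rng), 0.1)
        with pytest.raises(ValueError, match="background"):
            sd.estimate_and_remove_scatter(proj, response=A)

    def test_margin_mask_identifies_miss_rays(self):
        g = sd.make_grid((6, 6, 6), 2.0)
        cams = three_cameras(10, 2.0)
        A = sd.build_response_matrix(g, cams)
        mask = margin_mask(A, "cam_top")
        # 10 pixels at 2 mm cover 20 mm; the 12 mm phantom leaves 2-pixel rims
        assert mask.sum() == 10 * 10 - 6 * 6


class TestWeightedDoseIntegral:
    def _setup(self, rng, lam=0.0):
        g = sd.make_grid((6, 6, 6), 2.0)
        cams = three_cameras(8, 2.0, lam=lam)
        A = sd.build_response_matrix(g, cams)
        ref_dose = sd.DoseVolume(g, 0.5 + rng.random(g.shape))
        ref_images = sd.forward_project(A, ref_dose, 0.0)
        ref = sd.ReferenceField(dose=ref_dose, images=ref_images)
        return g, A, ref

    def test_self_reference_identity(self, rng):
        g, A, ref = self._setup(rng)
        p, valid = sd.weighted_dose_integral(ref.images, ref, A)
        expected = A.matrix @ ref.dose.ravel()
        assert np.allclose(p[valid], expected[valid], rtol=1e-12)

    def test_homogeneous_in_intensity(self, rng):
        g, A, ref = self._setup(rng)
        doubled = ref.images.with_images(
            {k: 2 * v for k, v in ref.images.images.items()})
        p, valid = sd.weighted_dose_integral(doubled, ref, A)
        expected = 2 * (A.matrix @ ref.dose.ravel())
        assert np.allclose(p[valid], expected[valid], rtol=1e-12)

    def test_end_to_end_consistency(self, rng):
        """Projecting any test dose through the same system and applying the
        reference-field ratio recovers A @ D_test."""
        g, A, ref = self._setup(rng)
        D_test = sd.DoseVolume(g, rng.random(g.shape))
        I_test = sd.forward_project(A, D_test, 0.0)
        p, valid = sd.weighted_dose_integral(I_test, ref, A)
        expected = A.matrix @ D_test.ravel()
        rel = np.abs(p[valid] - expected[valid]) / np.maximum(expected[valid], 1e-300)
        assert rel.max() < 1e-6

    def test_all_pixels_excluded_errors(self, rng):
        g, A, ref = self._setup(rng)
        dark = ref.images.with_images(
            {k: np.zeros_like(v) for k, v in ref.images.images.items()})
        dark_ref = sd.ReferenceField(dose=ref.dose, images=dark)
        with pytest.raises(ValueError, match="no usable"):
            sd.weighted_dose_integral(ref.images, dark_ref, A)


class TestDoseScaleCalibration:
    def test_identity_scale(self, small_grid, rng):
        D = sd.DoseVolume(small_grid, 1.0 + rng.random(small_grid.shape))
        scale, cal = sd.calibrate_dose_scale(D, D)
        assert np.isclose(scale, 1.0)
        assert np.allclose(cal.values, D.values)

    def test_known_factor_recovered(self, small_grid, rng):
        ref = sd.DoseVolume(small_grid, 1.0 + rng.random(small_grid.shape))
        k = 3.7
        D0 = sd.DoseVolume(small_grid, ref.values / k)
        scale, cal = sd.calibrate_dose_scale(D0, ref)
        assert np.isclose(scale, k)
        assert np.allclose(cal.values, ref.values, rtol=1e-12)

    def test_zero_region_mean_errors(self, small_grid):
        zero = sd.DoseVolume(small_grid, np.zeros(small_grid.shape))
        ref = sd.DoseVolume(small_grid, np.ones(small_grid.shape))
        with pytest.raises(ValueError, match="zero mean"):
            sd.calibrate_dose_scale(zero, ref)
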