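"""LASSO-TV solver tests: oracles, limits, recovery, time series."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

import scintidose as sd
from _oracles import lasso_tv_convex_oracle, tv_brute_force
from conftest import three_cameras
from scintidose.reconstruction import tv_prox
from scipy.optimize import nnls


class TestTotalVariation:
    def test_constant_volume_zero(self):
        assert sd.total_variation(np.full((4, 5, 6), 3.2)) == 0.0
        assert sd.total_variation(np.full((4, 5, 6), 3.2), "anisotropic") == 0.0

    def test_single_edge(self):
        x = np.zeros((2, 1, 1))
        x[1] = 1.0
        assert sd.total_variation(x, "isotropic") == 1.0
        assert sd.total_variation(x, "anisotropic") == 1.0

    @pytest.mark.parametrize("flavor", ["isotropic", "anisotropic"])
    def test_matches_brute_force(self, flavor, rng):
        x = rng.random((3, 3, 3))
        assert np.isclose(sd.total_variation(x, flavor),
                          tv_brute_force(x, flavor), rtol=1e-12)

    def test_positive_homogeneity(self, rng):
        x = rng.random((4, 4, 4))
        assert np.isclose(sd.total_variation(3.5 * x), 3.5 * sd.total_variation(x))


class TestTvProx:
    def test_zero_weight_is_projection(self, rng):
        b = rng.normal(size=(4, 4, 4))
        out = tv_prox(b, 0.0, nonneg=True)
        assert np.array_equal(out, np.clip(b, 0, None))

    def test_prox_decreases_objective(self, rng):
        b = rng.normal(size=(5, 5, 5)) + 0.5
        w = 0.3
        out = tv_prox(b, w, n_iters=100)

        def obj(x):
            return 0.5 * ((x - b) ** 2).sum() + w * sd.total_variation(x)

        assert obj(out) < obj(np.clip(b, 0, None))
        assert np.all(out >= 0)


class TestLassoTvSolve:
    def test_identity_system_recovers_data(self, rng):
        p = np.abs(rng.normal(1.0, 0.3, 27))
        cfg = sd.SolverConfig(alpha=0.0, beta=0.0, max_iters=500, tol=1e-12)
        res = sd.lasso_tv_solve(np.eye(27), p, cfg, shape=(3, 3, 3))
        assert np.abs(res.dose.ravel() - p).max() < 1e-6

    def test_matches_sklearn_lasso_alpha_zero(self, rng):
        """With no TV term the problem is a positive LASSO; the attained
        objective must match scikit-learn's coordinate-descent solver."""
        A = rng.random((8, 27))
        p = rng.random(8)
        beta = 0.01 * np.abs(A.T @ p).max()
        cfg = sd.SolverConfig(alpha=0.0, beta=beta, max_iters=5000, tol=1e-14)
        res = sd.lasso_tv_solve(A, p, cfg, shape=(3, 3, 3))

        def objective(x):
            r = A @ x - p
            return 0.5 * r @ r + beta * np.abs(x).sum()

        skl = Lasso(alpha=beta / 8, positive=True, tol=1e-12,
                    max_iter=100000, fit_intercept=False).fit(A, p)
        f_mine = objective(res.dose.ravel())
        f_skl = objective(skl.coef_)
        assert f_mine <= f_skl * (1 + 1e-4)
        assert abs(f_mine - f_skl) / f_skl < 1e-4

    @pytest.mark.parametrize("shape,flavor", [
        ((2, 2, 2), "anisotropic"),
        ((3, 3, 3), "isotropic"),
        ((4, 4, 4), "anisotropic"),
        ((4, 4, 4), "isotropic"),
    ])
    def test_matches_convex_oracle(self, shape, flavor, rng):
        """On small systems the attained objective agrees with an
        independent general-purpose convex solve to 0.01%."""
        m = int(np.prod(shape))
        A = rng.random((m // 2 + 3, m))
        p = rng.random(m // 2 + 3) * 2.0
        scale = np.abs(A.T @ p).max()
        alpha, beta = 1e-2 * scale, 1e-3 * scale
        f_oracle = lasso_tv_convex_oracle(A, p, alpha, beta, shape, flavor)
        cfg = sd.SolverConfig(alpha=alpha, beta=beta, max_iters=4000, tol=1e-13,
                              tv_flavor=flavor, tv_iters=60)
        res = sd.lasso_tv_solve(A, p, cfg, shape=shape)
        f_mine = res.objective_trace[-1]
        assert f_mine <= 1.0001 * f_oracle

    def test_objective_monotone_nonincreasing(self, rng):
        g = sd.make_grid((10, 10, 10), 2.0)
        cams = three_cameras(10, 2.0)
        A = sd.build_response_matrix(g, cams)
        truth = sd.DoseVolume(g, rng.random(g.shape))
        p = sd.forward_project(A, truth).vector
        p = p * (1 + 0.02 * rng.standard_normal(p.size))  # noisy data
        p = np.clip(p, 0, None)
        res = sd.lasso_tv_solve(A, p, sd.SolverConfig(max_iters=200, tol=1e-12))
        tr = res.objective_trace
        rel_increase = np.diff(tr) / np.maximum(tr[:-1], 1e-30)
        assert rel_increase.max() <= 1e-8

    def test_result_nonnegative_exactly(self, rng):
        A = rng.normal(size=(10, 27))
        p = rng.normal(size=10)
        res = sd.lasso_tv_solve(A, p, sd.SolverConfig(max_iters=300), shape=(3, 3, 3))
        assert res.dose.values.min() >= 0.0

    def test_vanishing_regularization_approaches_nnls(self, rng):
        """As alpha, beta -> 0 on a full-rank system the solution tends to
        the nonnegative least-squares solution."""
        A = rng.random((40, 27)) + 0.1
        x_true = np.clip(rng.normal(0.5, 0.5, 27), 0, None)
        p = A @ x_true
        x_nnls, _ = nnls(A, p)
        prev_dist = np.inf
        for eps in (1e-2, 1e-4, 1e-6, 1e-8):
            scale = np.abs(A.T @ p).max()
            cfg = sd.SolverConfig(alpha=eps * scale, beta=eps * scale,
                                  max_iters=8000, tol=1e-15, tv_iters=40)
            res = sd.lasso_tv_solve(A, p, cfg, shape=(3, 3, 3))
            dist = np.linalg.norm(res.dose.ravel() - x_nnls)
            assert dist < prev_dist + 1e-9
            prev_dist = dist
        assert prev_dist < 1e-3 * np.linalg.norm(x_nnls)

    def test_nested_cube_phantom_recovery(self):
        """Noise-free three-view reconstruction of a piecewise-constant
        nested-cube phantom is accurate to < 2% RMS of the maximum dose."""
        g = sd.make_grid((20, 20, 20), 2.0)
        vals = np.zeros(g.shape)
        vals[4:16, 4:16, 4:16] = 1.0
        vals[8:12, 8:12, 8:12] = 2.0
        truth = sd.DoseVolume(g, vals)
        A = sd.build_response_matrix(g, three_cameras(20, 2.0))
        p = sd.forward_project(A, truth).vector
        scale = np.abs(A.matrix.T @ p).max()
        cfg = sd.SolverConfig(alpha=1e-4 * scale, beta=1e-5 * scale,
                              max_iters=1500, tol=1e-11, tv_iters=20)
        res = sd.lasso_tv_solve(A, p, cfg)
        rms = np.sqrt(((res.dose.values - truth.values) ** 2).mean())
        assert rms < 0.02 * truth.max

    def test_estimator_sklearn_interface(self, rng):
        est = sd.LassoTVReconstructor(alpha=0.0, beta=0.1, max_iters=50)
        params = est.get_params()
        assert params["beta"] == 0.1
        est.set_params(max_iters=60)
        A = rng.random((10, 8))
        est.fit(A, rng.random(10), shape=(2, 2, 2))
        assert est.coef_.shape == (8,)
        assert est.objective_trace_.size >= 1
        assert est.n_iter_ <= 60


class TestTimeSeries:
    def _system(self, rng):
        g = sd.make_grid((12, 12, 12), 4.0)
        beam = sd.BeamSpec(field_size=(30, 30), penumbra_sigma=2.0,
                           attenuation_mu=0.005, duration=10.0)
        dose = sd.generate_beam_dose(g, beam)
        A = sd.build_response_matrix(g, three_cameras(12, 4.0))
        return g, beam, dose, A

    def test_single_frame_matches_direct_solve(self, rng):
        g, beam, dose, A = self._system(rng)
        p = sd.forward_project(A, dose).vector
        cfg = sd.SolverConfig(max_iters=400, tol=1e-10)
        results, cum = sd.solve_timeseries(A, [p], cfg)
        direct = sd.lasso_tv_solve(A, p, cfg)
        assert np.allclose(cum.values, direct.dose.values)

    def test_equal_frames_sum_linearly(self, rng):
        g, beam, dose, A = self._system(rng)
        frames = [sd.forward_project(A, dose * 0.1).vector] * 10
        cfg = sd.SolverConfig(max_iters=400, tol=1e-10)
        _, cum = sd.solve_timeseries(A, frames, cfg)
        single = sd.lasso_tv_solve(A, frames[0], cfg)
        rms = np.sqrt(((cum.values - 10 * single.dose.values) ** 2).mean())
        assert rms < 0.01 * cum.max

    def test_imrt_frames_localize_to_beam_footprints(self):
        """Each reconstructed frame concentrates in its own beam's in-field
        region (dilated by the 3 mm clinical distance criterion)."""
        from scipy.ndimage import binary_dilation

        g = sd.make_grid((16, 16, 16), 4.0)
        beams = [sd.BeamSpec(gantry_angle=a, field_size=(28, 28),
                             penumbra_sigma=1.0, attenuation_mu=0.005, duration=1.0)
                 for a in (270.0, 230.0, 310.0)]
        total, per_beam = sd.generate_plan_dose(g, beams)
        A = sd.build_response_matrix(g, three_cameras(16, 4.0))
        frames = [sd.forward_project(A, d).vector for d in per_beam]
        cfg = sd.SolverConfig(max_iters=400, tol=1e-10)
        results, cum = sd.solve_timeseries(A, frames, cfg)
        for res, beam_dose in zip(results, per_beam):
            mask = beam_dose.values > 1e-6
            mask = binary_dilation(mask, iterations=1)  # 4 mm voxel >= 3 mm
            frac = res.dose.values[mask].sum() / max(res.dose.total, 1e-300)
            assert frac >= 0.90

    def test_empty_frames_rejected(self, rng):
        A = rng.random((4, 8))
        with pytest.raises(ValueError):
            sd.solve_timeseries(A, [])
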