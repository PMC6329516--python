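"""CG inner solver, ADMM fixed points, TV configuration, FDK baseline."""

import numpy as np
import pytest

import tfct
from tfct.errors import ValidationError
from tfct.phantoms import EllipsoidSpec, PhantomSpec, rasterize, simulate_scan
from tfct.reconstruction import cg_solve
from conftest import dense_matrix


class TestCG:
    def test_scaled_identity_solved_in_one_iteration(self, rng):
        b = rng.normal(size=(6, 6, 6))
        x, info = cg_solve(lambda v: 2.0 * v, b, max_iter=5, tol=1e-12)
        assert np.allclose(x, b / 2.0)
        assert info.iterations == 1
        assert info.converged

    def test_matches_dense_solve_on_tiny_system(self, rng, tiny_system):
        grid, geom = tiny_system
        a = dense_matrix(grid, geom)
        mu = 0.5
        normal = a.T @ a + mu * np.eye(a.shape[1])
        b = rng.normal(size=grid.shape)
        x_dense = np.linalg.solve(normal, b.ravel()).reshape(grid.shape)

        def op(v):
            av = tfct.forward_project(tfct.Volume(v, grid), geom).data
            return tfct.back_project(tfct.Sinogram(av, geom), grid).data + mu * v

        x_cg, info = cg_solve(op, b, max_iter=600, tol=1e-9)
        assert np.linalg.norm(x_cg - x_dense) / np.linalg.norm(x_dense) < 1e-6

    def test_residual_history_nonincreasing(self, rng):
        n = 40
        m = rng.normal(size=(n, n))
        spd = m @ m.T + n * np.eye(n)
        b = rng.normal(size=(n, 1, 1))
        _, info = cg_solve(lambda v: (spd @ v.ravel()).reshape(v.shape), b,
                           max_iter=30, tol=1e-14)
        hist = np.array(info.residual_history)
        assert np.all(np.diff(hist) <= 1e-8)

    def test_nonfinite_rhs_rejected(self):
        bad = np.zeros((4, 4, 4))
        bad[0, 0, 0] = np.inf
        with pytest.raises(ValidationError):
            cg_solve(lambda v: v, bad)


@pytest.fixture(scope="module")
def tiny_problem(tiny_system):
    grid, geom = tiny_system
    spec = PhantomSpec((EllipsoidSpec((0, 0, 0), (12, 10, 10), 0.02),))
    truth = rasterize(spec, grid)
    sino = simulate_scan(spec, geom, grid=grid)
    return grid, geom, truth, sino


class TestADMM:
    def test_unregularized_limit_reaches_least_squares(self, tiny_problem):
        """lambda = 0, noiseless, full views: fidelity -> 0 (relative)."""
        grid, geom, truth, sino = tiny_problem
        cfg = tfct.ADMMConfig(weights=0.0, mu=0.05, levels=1,
                              outer_iterations=40, cg_iterations=30)
        res = tfct.admm_reconstruct(sino, grid, cfg)
        ynorm = np.linalg.norm(sino.data / np.abs(sino.data).max())
        assert np.sqrt(2 * res.fidelity_trace[-1]) / ynorm < 1e-4

    def test_lambda_zero_fixed_point_solves_normal_equations(self, tiny_problem):
        """The lambda=0 ADMM fixed point satisfies A^T A x = A^T y against a
        dense-matrix oracle, to CG tolerance."""
        grid, geom, truth, sino = tiny_problem
        cfg = tfct.ADMMConfig(weights=0.0, mu=0.05, levels=1,
                              outer_iterations=60, cg_iterations=30,
                              cg_tolerance=1e-8)
        res = tfct.admm_reconstruct(sino, grid, cfg)
        a = dense_matrix(grid, geom)
        scale = float(np.abs(sino.data).max())
        x = (res.volume.data / scale).ravel()
        y = (sino.data / scale).ravel()
        resid = a.T @ (a @ x - y)
        assert np.linalg.norm(resid) / np.linalg.norm(a.T @ y) < 1e-4

    def test_objective_trace_eventually_nonincreasing(self, tiny_problem):
        """Split Bregman is not strictly monotone; with a sufficiently large
        coupling mu the objective is non-increasing after a short burn-in."""
        grid, geom, truth, sino = tiny_problem
        cfg = tfct.ADMMConfig(weights=1e-3, mu=2.0, levels=2, outer_iterations=25)
        res = tfct.admm_reconstruct(sino, grid, cfg)
        obj = np.array(res.objective_trace)
        rel_upticks = np.diff(obj[3:]) / np.abs(obj[3:-1])
        assert np.all(rel_upticks <= 1e-6)

    def test_determinism_bit_identical(self, tiny_problem):
        grid, geom, truth, sino = tiny_problem
        cfg = tfct.ADMMConfig(weights=1e-3, mu=1.0, levels=2, outer_iterations=5)
        r1 = tfct.admm_reconstruct(sino, grid, cfg)
        r2 = tfct.admm_reconstruct(sino, grid, cfg)
        assert r1.objective_trace == r2.objective_trace
        assert np.array_equal(r1.volume.data, r2.volume.data)

    def test_traces_have_run_length(self, tiny_problem):
        grid, geom, truth, sino = tiny_problem
        cfg = tfct.ADMMConfig(weights=1e-3, outer_iterations=7)
        res = tfct.admm_reconstruct(sino, grid, cfg)
        assert res.iterations_run == 7
        assert len(res.objective_trace) == len(res.fidelity_trace) == 7

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            tfct.ADMMConfig(mu=0.0)
        with pytest.raises(ValidationError):
            tfct.ADMMConfig(outer_iterations=0)
        with pytest.raises(ValidationError):
            tfct.ADMMConfig(init="warm")


class TestTV:
    def test_tv_penalty_equals_isotropic_tv_constant(self, rng):
        """The TV weight pattern reproduces the central-difference isotropic TV
        norm up to the documented constant (checked through tf_norm)."""
        from tfct.framelet import RegWeights, tf_forward, tf_norm
        x = rng.normal(size=(9, 8, 7))
        val = tf_norm(tf_forward(x, 1), RegWeights.tv(1.0))
        grads = [(np.roll(x, 1, a) - np.roll(x, -1, a)) / 2.0 for a in range(3)]
        tv = float(np.sqrt(sum(g ** 2 for g in grads)).sum())
        const = (1 / np.sqrt(3)) * (np.sqrt(2) / 2)  # = sqrt(6)/6
        assert val == pytest.approx(tv * const, rel=1e-10)

    def test_large_lambda_flattens_reconstruction(self, tiny_problem):
        """TV norm of the converged output decreases monotonically over a
        3-point lambda sweep (the coupling mu is scaled with lambda, as the
        splitting needs for strong regularization)."""
        grid, geom, truth, sino = tiny_problem
        from tfct.framelet import RegWeights, tf_forward, tf_norm
        tv_norms = []
        for lam, mu in ((1e-2, 1.0), (1.0, 5.0), (10.0, 20.0)):
            cfg = tfct.ADMMConfig(weights=lam, mu=mu, levels=1, outer_iterations=150)
            res = tfct.tv_reconstruct(sino, grid, cfg)
            tv_norms.append(tf_norm(tf_forward(res.volume.data, 1), RegWeights.tv(1.0)))
        assert tv_norms[2] < tv_norms[1] < tv_norms[0]

    def test_delegates_with_single_level(self, tiny_problem):
        grid, geom, truth, sino = tiny_problem
        cfg = tfct.ADMMConfig(weights=1e-3, levels=3, outer_iterations=3)
        res = tfct.tv_reconstruct(sino, grid, cfg)  # levels overridden to 1
        assert res.iterations_run == 3


class TestFDK:
    # grid kept inside the one-rotation scan's z-coverage (+-24 mm here)
    _grid = tfct.VolumeGrid(32, 32, 20, 2.0, 2.0, 2.0)

    def test_zero_sinogram_gives_zero_volume(self, small_geometry):
        zero = tfct.Sinogram(np.zeros((48, 8, 48)), small_geometry)
        vol = tfct.fdk_reconstruct(zero, self._grid)
        assert np.all(vol.data == 0.0)

    def test_linearity_in_sinogram(self, rng, small_geometry):
        y1 = rng.normal(size=(48, 8, 48))
        y2 = rng.normal(size=(48, 8, 48))
        f = lambda y: tfct.fdk_reconstruct(tfct.Sinogram(y, small_geometry), self._grid).data
        assert np.allclose(f(y1 + 0.5 * y2), f(y1) + 0.5 * f(y2), atol=1e-9)

    def test_uniform_sphere_center_value(self):
        """Dense-view helical FDK recovers the center attenuation within 5%."""
        grid = tfct.desk_grid()
        geom = tfct.desk_geometry(n_turns=2.0)
        mu = 0.02
        spec = PhantomSpec((EllipsoidSpec((0, 0, 0), (30, 30, 20), mu),))
        sino = simulate_scan(spec, geom, grid=grid)
        vol = tfct.fdk_reconstruct(sino, grid)
        center = vol.data[31:33, 31:33, 15:17].mean()
        assert center == pytest.approx(mu, rel=0.05)

    def test_insufficient_rotation_rejected(self, small_grid, small_geometry):
        import dataclasses
        short = dataclasses.replace(small_geometry, n_views=10)
        zero = tfct.Sinogram(np.zeros((10, 8, 48)), short)
        with pytest.raises(ValidationError):
            tfct.fdk_reconstruct(zero, small_grid)

    def test_uncovered_slices_reported(self, small_geometry):
        """A grid far beyond the scanned z-range names the uncovered slices."""
        far = tfct.VolumeGrid(16, 16, 8, 2, 2, 2, origin=(0, 0, 800.0))
        zero = tfct.Sinogram(np.zeros((48, 8, 48)), small_geometry)
        with pytest.raises(ValidationError, match="slices"):
            tfct.fdk_reconstruct(zero, far)
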