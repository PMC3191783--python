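import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from rmcflow import (
    GridSpec,
    ModelParams,
    NonlinearResidualOperator,
    SegmentationState,
    assemble_si_system,
    assemble_spatial_operator,
    compute_edge_field,
    explicit_cfl_bound,
    explicit_step,
    implicit_residual,
    nonlinear_rhs,
)
from rmcflow.edge import EdgeField

from conftest import dense_operator_oracle, random_smooth_field


def unit_edge(grid):
    return EdgeField(g=np.ones(grid.shape))


def five_point_laplacian(grid):
    """Independent dense -Laplacian on interior cells (Dirichlet)."""
    nxi, nyi = grid.nx - 2, grid.ny - 2
    n = nxi * nyi
    L = np.zeros((n, n))
    for m in range(nyi):
        for l in range(nxi):
            k = m * nxi + l
            L[k, k] = 2 / grid.hx**2 + 2 / grid.hy**2
            if l > 0:
                L[k, k - 1] = -1 / grid.hx**2
            if l < nxi - 1:
                L[k, k + 1] = -1 / grid.hx**2
            if m > 0:
                L[k, k - nxi] = -1 / grid.hy**2
            if m < nyi - 1:
                L[k, k + nxi] = -1 / grid.hy**2
    return L


class TestSpatialOperator:
    def test_unit_coefficients_give_scaled_laplacian(self):
        grid = GridSpec(5, 5)
        params = ModelParams()
        u_ref = np.zeros(grid.shape)
        A = assemble_spatial_operator(u_ref, unit_edge(grid), params, grid)
        np.testing.assert_allclose(A.toarray(), five_point_laplacian(grid),
                                   rtol=1e-13)

    def test_matches_dense_loop_oracle_on_random_field(self, params):
        grid = GridSpec(7, 6)
        rng = np.random.default_rng(5)
        u_ref = random_smooth_field(grid, rng)
        g = 1.0 / (1.0 + rng.random(grid.shape))
        edge = EdgeField(g=g)
        A = assemble_spatial_operator(u_ref, edge, params, grid)
        oracle = dense_operator_oracle(u_ref, g, params.epsilon, grid)
        np.testing.assert_allclose(A.toarray(), oracle, rtol=1e-12, atol=1e-12)

    def test_five_point_pattern_symmetric(self, params):
        grid = GridSpec(8, 8)
        rng = np.random.default_rng(1)
        A = assemble_spatial_operator(random_smooth_field(grid, rng),
                                      unit_edge(grid), params, grid)
        nnz_per_row = np.diff(A.indptr)
        assert nnz_per_row.max() <= 5
        pattern = (A != 0).astype(int)
        assert (pattern != pattern.T).nnz == 0

    def test_constant_field_annihilated_away_from_boundary(self, params):
        grid = GridSpec(8, 8)
        u_ref = np.full(grid.shape, 0.7)
        u_ref[0, :] = u_ref[-1, :] = u_ref[:, 0] = u_ref[:, -1] = 0.0
        A = assemble_spatial_operator(np.zeros(grid.shape), unit_edge(grid),
                                      params, grid)
        out = (A @ np.ones(grid.n_interior)).reshape(grid.ny - 2, grid.nx - 2)
        # interior-of-interior rows see a constant vector and return zero
        np.testing.assert_allclose(out[1:-1, 1:-1], 0.0, atol=1e-9)
        assert np.all(out[0, :] > 0)  # boundary-adjacent rows keep Dirichlet term

    def test_shape_mismatch_rejected(self, params):
        grid = GridSpec(8, 8)
        with pytest.raises(ValueError):
            assemble_spatial_operator(np.zeros((4, 4)), unit_edge(grid),
                                      params, grid)


class TestSemiImplicitSystem:
    def test_zero_step_is_identity(self, phantom64, edge64, params):
        grid = phantom64.grid
        rng = np.random.default_rng(2)
        prev = SegmentationState(u=random_smooth_field(grid, rng))
        system = assemble_si_system(prev, edge64, params, grid, dtau=0.0)
        x = spla.spsolve(system.matrix.tocsc(), system.rhs)
        np.testing.assert_allclose(x, grid.pack(prev.u), atol=1e-14)

    def test_flat_state_row_sums(self, params):
        grid = GridSpec(5, 5)
        prev = SegmentationState(u=np.zeros(grid.shape))
        system = assemble_si_system(prev, unit_edge(grid), params, grid, dtau=0.1)
        expected = np.eye(grid.n_interior) + 0.1 * five_point_laplacian(grid)
        np.testing.assert_allclose(system.matrix.toarray(), expected, rtol=1e-13)
        # the center row has no boundary neighbor: row sum exactly 1
        rs = np.asarray(system.matrix.sum(axis=1)).ravel()
        assert rs[4] == pytest.approx(1.0, abs=1e-13)

    @pytest.mark.parametrize("seed", range(5))
    def test_m_matrix_invariants(self, edge64, params, phantom64, seed):
        grid = phantom64.grid
        rng = np.random.default_rng(seed)
        prev = SegmentationState(u=random_smooth_field(grid, rng))
        HS = assemble_si_system(prev, edge64, params, grid, dtau=0.16).matrix
        d = HS.diagonal()
        assert np.all(d > 0)
        off = HS - sp.diags(d)
        assert off.nnz == 0 or off.data.max() <= 1e-15
        row_abs_off = np.asarray(np.abs(off).sum(axis=1)).ravel()
        assert np.all(d >= row_abs_off - 1e-12)

    def test_maximum_principle(self, edge64, params, phantom64):
        grid = phantom64.grid
        rng = np.random.default_rng(11)
        prev = SegmentationState(u=random_smooth_field(grid, rng))
        system = assemble_si_system(prev, edge64, params, grid, dtau=0.16)
        u_new = spla.spsolve(system.matrix.tocsc(), system.rhs)
        assert u_new.min() >= min(0.0, prev.u.min()) - 1e-12
        assert u_new.max() <= max(0.0, prev.u.max()) + 1e-12

    def test_negative_dtau_rejected(self, edge64, params, phantom64):
        prev = SegmentationState(u=np.zeros(phantom64.grid.shape))
        with pytest.raises(ValueError):
            assemble_si_system(prev, edge64, params, phantom64.grid, dtau=-0.1)


class TestExplicitStep:
    def test_zero_step_and_zero_state_fixed_points(self, edge64, params, phantom64):
        grid = phantom64.grid
        rng = np.random.default_rng(3)
        prev = SegmentationState(u=random_smooth_field(grid, rng))
        same = explicit_step(prev, edge64, params, grid, dtau=0.0)
        np.testing.assert_array_equal(same.u, prev.u)
        zero = SegmentationState(u=np.zeros(grid.shape))
        out = explicit_step(zero, edge64, params, grid, dtau=1e-5, cfl="ignore")
        np.testing.assert_array_equal(out.u, 0.0)

    def test_explicit_vs_semi_implicit_difference_is_second_order(
        self, edge64, params, seed64, phantom64
    ):
        grid = phantom64.grid
        prev = SegmentationState(u=seed64)
        diffs = []
        for dtau in (2e-6, 1e-6):
            ex = explicit_step(prev, edge64, params, grid, dtau=dtau)
            system = assemble_si_system(prev, edge64, params, grid, dtau=dtau)
            si = grid.unpack(spla.spsolve(system.matrix.tocsc(), system.rhs))
            diffs.append(np.linalg.norm(ex.u - si))
        ratio = diffs[0] / diffs[1]
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_cfl_guard(self, edge64, params, seed64, phantom64):
        grid = phantom64.grid
        prev = SegmentationState(u=seed64)
        bound = explicit_cfl_bound(seed64, edge64, params, grid)
        with pytest.warns(UserWarning):
            explicit_step(prev, edge64, params, grid, dtau=2 * bound)
        with pytest.raises(ValueError):
            explicit_step(prev, edge64, params, grid, dtau=2 * bound, cfl="error")


class TestImplicitResidual:
    def test_trivial_steady_state(self, edge64, params, phantom64):
        grid = phantom64.grid
        prev = SegmentationState(u=np.zeros(grid.shape))
        r = implicit_residual(np.zeros(grid.shape), prev, edge64, params, grid,
                              dtau=0.1)
        np.testing.assert_array_equal(r, 0.0)

    def test_si_solution_residual_vanishes_linearly(self, edge64, params,
                                                    seed64, phantom64):
        grid = phantom64.grid
        prev = SegmentationState(u=seed64)
        norms = []
        for dtau in (2e-5, 1e-5):
            system = assemble_si_system(prev, edge64, params, grid, dtau=dtau)
            si = grid.unpack(spla.spsolve(system.matrix.tocsc(), system.rhs))
            r = implicit_residual(si, prev, edge64, params, grid, dtau=dtau)
            norms.append(np.linalg.norm(r) / dtau)
        # residual/dtau itself shrinks roughly linearly with dtau
        assert norms[1] < 0.65 * norms[0]

    def test_consistency_with_assembled_operator(self, edge64, params, phantom64):
        grid = phantom64.grid
        rng = np.random.default_rng(4)
        u = random_smooth_field(grid, rng)
        A = assemble_spatial_operator(u, edge64, params, grid)
        f = nonlinear_rhs(u, edge64, params, grid)
        np.testing.assert_allclose(grid.pack(f), -(A @ grid.pack(u)),
                                   rtol=1e-12, atol=1e-12)

    def test_evaluation_counter_increments(self, edge64, params, phantom64):
        grid = phantom64.grid
        prev = SegmentationState(u=np.zeros(grid.shape))
        op = NonlinearResidualOperator(prev, edge64, params, grid, dtau=0.1)
        assert op.n_evals == 0
        op(np.zeros(grid.n_interior))
        op(np.zeros(grid.n_interior))
        assert op.n_evals == 2


@pytest.fixture(scope="module")
def heat_limit_setup():
    grid = GridSpec(32, 32)
    params = ModelParams(epsilon=1e3)
    rng = np.random.default_rng(8)
    u_prev = random_smooth_field(grid, rng)
    L = five_point_laplacian(grid)
    return grid, params, u_prev, L


class TestLinearLimit:
    """With g = 1 and eps = 1e3 the flow reduces to the heat equation."""

    def test_semi_implicit_matches_backward_euler_heat(self, heat_limit_setup):
        grid, params, u_prev, L = heat_limit_setup
        dtau = 0.01
        prev = SegmentationState(u=u_prev)
        system = assemble_si_system(prev, unit_edge(grid), params, grid, dtau=dtau)
        u_si = spla.spsolve(system.matrix.tocsc(), system.rhs)
        oracle = np.linalg.solve(np.eye(grid.n_interior) + dtau * L,
                                 grid.pack(u_prev))
        assert np.linalg.norm(u_si - oracle) <= 1e-3 * np.linalg.norm(oracle)

    def test_implicit_matches_crank_nicolson_heat(self, heat_limit_setup):
        from rmcflow import JFNKConfig, jfnk_solve

        grid, params, u_prev, L = heat_limit_setup
        dtau = 0.01
        prev = SegmentationState(u=u_prev)
        op = NonlinearResidualOperator(prev, unit_edge(grid), params, grid,
                                       dtau=dtau)
        cfg = JFNKConfig(newton_tol=1e-12, inner_rtol=1e-10, inner_maxiter=100)
        u_i, rep = jfnk_solve(op, grid.pack(u_prev), cfg)
        assert rep.converged
        I = np.eye(grid.n_interior)
        oracle = np.linalg.solve(I + 0.5 * dtau * L,
                                 (I - 0.5 * dtau * L) @ grid.pack(u_prev))
        assert np.linalg.norm(u_i - oracle) <= 1e-3 * np.linalg.norm(oracle)
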