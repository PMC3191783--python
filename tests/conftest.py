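import numpy as np
import pytest

from rmcflow import (
    GridSpec,
    ModelParams,
    compute_edge_field,
    generate_phantom,
    make_seed_function,
)


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom(64, seed=1)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def edge64(phantom64, params):
    return compute_edge_field(phantom64.image, params, phantom64.grid)


@pytest.fixture(scope="session")
def seed64(phantom64):
    return make_seed_function(phantom64.grid, (0.5, 0.5), 0.15)


def random_smooth_field(grid: GridSpec, rng: np.random.Generator,
                        amplitude: float = 1.0) -> np.ndarray:
    """Seeded random field, smoothed and zeroed on the boundary."""
    from scipy.ndimage import gaussian_filter

    u = gaussian_filter(rng.standard_normal(grid.shape), 2.0)
    u *= amplitude / max(np.abs(u).max(), 1e-30)
    u[0, :] = u[-1, :] = 0.0
    u[:, 0] = u[:, -1] = 0.0
    return u


def dense_operator_oracle(u_ref: np.ndarray, g: np.ndarray, eps: float,
                          grid: GridSpec) -> np.ndarray:
    """Loop-based dense assembly of -Q div(g grad(.)/q) on interior cells.

    Independent of the sparse vectorized path: derivatives, face averages and
    matrix entries are computed cell by cell.
    """
    ny, nx = grid.shape
    hx, hy = grid.hx, grid.hy

    def ddx(u, m, l):
        if l == 0:
            return (u[m, 1] - u[m, 0]) / hx
        if l == nx - 1:
            return (u[m, -1] - u[m, -2]) / hx
        return (u[m, l + 1] - u[m, l - 1]) / (2 * hx)

    def ddy(u, m, l):
        if m == 0:
            return (u[1, l] - u[0, l]) / hy
        if m == ny - 1:
            return (u[-1, l] - u[-2, l]) / hy
        return (u[m + 1, l] - u[m - 1, l]) / (2 * hy)

    q = np.empty((ny, nx))
    for m in range(ny):
        for l in range(nx):
            q[m, l] = np.sqrt(eps**2 + ddx(u_ref, m, l) ** 2 + ddy(u_ref, m, l) ** 2)

    nxi, nyi = nx - 2, ny - 2
    A = np.zeros((nxi * nyi, nxi * nyi))

    def k(m, l):
        return (m - 1) * nxi + (l - 1)

    for m in range(1, ny - 1):
        for l in range(1, nx - 1):
            row = k(m, l)
            Q = q[m, l]
            for (mm, ll, h2) in (
                (m, l + 1, hx**2), (m, l - 1, hx**2),
                (m + 1, l, hy**2), (m - 1, l, hy**2),
            ):
                w = ((g[m, l] + g[mm, ll]) / 2) / ((q[m, l] + q[mm, ll]) / 2)
                A[row, row] += Q * w / h2
                if 1 <= mm <= ny - 2 and 1 <= ll <= nx - 2:
                    A[row, k(mm, ll)] -= Q * w / h2
    return A
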