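"""Algebraic multigrid preconditioner (smoothed aggregation, V-cycle).

A purely algebraic hierarchy is built from the fine-level matrix alone:
nodes are greedily grouped into aggregates over the strong-connection graph,
the piecewise-constant tentative prolongator is smoothed by one damped-Jacobi
step, restriction is the transpose, and every coarse operator is the exact
Galerkin triple product ``A_{lv+1} = R_lv A_lv P_lv``.  The V-cycle uses one
damped-Jacobi pre- and post-smoothing sweep and a direct solve on the
coarsest level; one cycle applied to the zero initial guess serves as the
preconditioner inside GMRES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass
class AMGConfig:
    """Hierarchy and smoother parameters.

    max_levels : depth cap (default 25).
    coarse_size : stop coarsening at or below this many unknowns.
    theta : strength-of-connection drop tolerance (0 keeps all couplings).
    jacobi_omega : damping of the pre/post relaxation sweeps.
    """

    max_levels: int = 25
    coarse_size: int = 40
    theta: float = 0.1
    jacobi_omega: float = 2.0 / 3.0
    prolongator_smoothing: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.max_levels:
            raise ValueError("max_levels must be at least 1")
        if not 0 < self.jacobi_omega < 2:
            raise ValueError("jacobi_omega must lie in (0, 2)")


@dataclass
class AMGLevel:
    A: sp.csr_matrix
    P: sp.csr_matrix | None = None  # to the next (coarser) level
    R: sp.csr_matrix | None = None


class AMGHierarchy:
    """Galerkin hierarchy of strictly shrinking operators."""

    def __init__(self, levels: list[AMGLevel], config: AMGConfig) -> None:
        self.levels = levels
        self.config = config
        self._coarse_lu = spla.splu(levels[-1].A.tocsc())

    @property
    def depth(self) -> int:
        return len(self.levels)

    def level_sizes(self) -> list[int]:
        return [lv.A.shape[0] for lv in self.levels]

    def _smooth(self, A: sp.csr_matrix, inv_diag: np.ndarray, b, x, sweeps=1):
        om = self.config.jacobi_omega
        for _ in range(sweeps):
            x = x + om * inv_diag * (b - A @ x)
        return x

    def vcycle(self, b: np.ndarray, x0: np.ndarray | None = None,
               _lv: int = 0) -> np.ndarray:
        """One V-cycle for ``A x = b`` starting from ``x0`` (zero if omitted)."""
        A = self.levels[_lv].A
        b = np.asarray(b, dtype=float)
        if b.shape[0] != A.shape[0]:
            raise ValueError("right-hand side size does not match level operator")
        if _lv == self.depth - 1:
            return self._coarse_lu.solve(b)
        x = np.zeros_like(b) if x0 is None else np.asarray(x0, dtype=float)
        if x.shape[0] != A.shape[0]:
            raise ValueError("initial guess size does not match level operator")
        inv_diag = 1.0 / A.diagonal()
        x = self._smooth(A, inv_diag, b, x)
        r = b - A @ x
        coarse = self.vcycle(self.levels[_lv].R @ r, None, _lv + 1)
        x = x + self.levels[_lv].P @ coarse
        return self._smooth(A, inv_diag, b, x)

    def solve(
        self, b: np.ndarray, rtol: float = 1e-7, max_cycles: int = 200
    ) -> tuple[np.ndarray, int]:
        """Stand-alone V-cycle iteration to relative residual ``rtol``.

        Returns ``(x, cycles)``; raises if the target is not met within
        ``max_cycles``.
        """
        A = self.levels[0].A
        b = np.asarray(b, dtype=float)
        bnorm = np.linalg.norm(b)
        if bnorm == 0:
            return np.zeros_like(b), 0
        x = np.zeros_like(b)
        for k in range(1, max_cycles + 1):
            x = self.vcycle(b, x)
            if np.linalg.norm(b - A @ x) <= rtol * bnorm:
                return x, k
        raise RuntimeError(f"AMG stand-alone solve missed rtol={rtol:g} "
                           f"in {max_cycles} cycles")

    def as_preconditioner(self) -> spla.LinearOperator:
        """LinearOperator applying one V-cycle from a zero initial guess."""
        n = self.levels[0].A.shape[0]
        return spla.LinearOperator((n, n), matvec=lambda r: self.vcycle(r))


def _aggregate(A: sp.csr_matrix, theta: float) -> np.ndarray:
    """Greedy standard aggregation; returns aggregate id per node (-1 none)."""
    n = A.shape[0]
    C = A.tocsr()
    diag = np.abs(C.diagonal())
    agg = np.full(n, -1, dtype=np.int64)
    indptr, indices, data = C.indptr, C.indices, C.data

    def strong_neighbors(i: int) -> np.ndarray:
        sl = slice(indptr[i], indptr[i + 1])
        cols, vals = indices[sl], data[sl]
        mask = cols != i
        if theta > 0:
            mask &= np.abs(vals) >= theta * np.sqrt(diag[i] * diag[cols])
        return cols[mask]

    # pass 1: seed aggregates from nodes whose neighborhood is untouched
    n_agg = 0
    for i in range(n):
        if agg[i] != -1:
            continue
        nbrs = strong_neighbors(i)
        if np.all(agg[nbrs] == -1):
            agg[i] = n_agg
            agg[nbrs] = n_agg
            n_agg += 1
    # pass 2: attach leftovers to a neighboring aggregate, else singleton
    for i in range(n):
        if agg[i] != -1:
            continue
        nbrs = strong_neighbors(i)
        joined = nbrs[agg[nbrs] != -1]
        if joined.size:
            agg[i] = agg[joined[0]]
        else:
            agg[i] = n_agg
            n_agg += 1
    return agg


def _estimate_rho(DinvA: spla.LinearOperator, n: int, iters: int = 10) -> float:
    x = np.ones(n) / np.sqrt(n)
    rho = 1.0
    for _ in range(iters):
        y = DinvA @ x
        ny = np.linalg.norm(y)
        if ny == 0:
            return 1.0
        rho, x = ny, y / ny
    return rho


def build_amg_hierarchy(A: sp.spmatrix, config: AMGConfig | None = None) -> AMGHierarchy:
    """Build a smoothed-aggregation hierarchy for a square sparse matrix.

    Level sizes strictly decrease and every coarse operator satisfies the
    Galerkin identity exactly; coarsening stops at ``coarse_size`` unknowns,
    at ``max_levels``, or when aggregation makes no further progress.
    """
    if config is None:
        config = AMGConfig()
    A = sp.csr_matrix(A)
    if A.shape[0] != A.shape[1]:
        raise ValueError("AMG requires a square matrix")
    levels = [AMGLevel(A=A)]
    while (levels[-1].A.shape[0] > config.coarse_size
           and len(levels) < config.max_levels):
        Af = levels[-1].A
        n = Af.shape[0]
        agg = _aggregate(Af, config.theta)
        n_agg = int(agg.max()) + 1
        if n_agg >= n:  # no progress; stop coarsening
            break
        T = sp.csr_matrix(
            (np.ones(n), (np.arange(n), agg)), shape=(n, n_agg)
        )
        if config.prolongator_smoothing:
            inv_diag = 1.0 / Af.diagonal()
            DinvA = sp.diags(inv_diag) @ Af
            rho = _estimate_rho(spla.aslinearoperator(DinvA), n)
            P = (sp.identity(n) - (4.0 / (3.0 * rho)) * DinvA) @ T
        else:
            P = T
        P = sp.csr_matrix(P)
        R = sp.csr_matrix(P.T)
        Ac = sp.csr_matrix(R @ Af @ P)
        levels[-1].P, levels[-1].R = P, R
        levels.append(AMGLevel(A=Ac))
    return AMGHierarchy(levels, config)


def amg_vcycle(h: AMGHierarchy, b: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
    """Functional alias for one V-cycle on the hierarchy's fine level."""
    return h.vcycle(b, x0)
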