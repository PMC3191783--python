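"""Jacobian-free Newton-Krylov solver for the implicit scheme.

Each scale step of the fully implicit (Crank-Nicolson) discretization
requires solving a nonlinear system ``HI(u) = 0``.  Newton's method is
applied without ever forming the Jacobian: the correction equation
``J(u) delta = -HI(u)`` is solved by GMRES, where each Jacobian-vector
product is probed by a first-order finite difference of the residual,

    J(u) v ~= (HI(u + rho v) - HI(u)) / rho,

with the perturbation ``rho = sqrt(eps_machine) * (1 + ||u||) / ||v||``.
Backtracking line search on the residual norm globalizes the iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .krylov import LinearSolveReport, gmres_solve


@dataclass
class JFNKConfig:
    """Newton/Krylov tolerances and line-search parameters.

    newton_tol : stopping tolerance on ``||HI(u)||_2`` (default 1e-10),
        interpreted relative to the initial residual when
        ``tol_mode="relative"`` (default) or as an absolute bound when
        ``tol_mode="absolute"``; ``newton_atol`` is an additional absolute
        floor guarding against over-solving an already converged step.
    inner_rtol, inner_restart : GMRES settings for the correction equation.
    ls_shrink, ls_c : backtracking factor in (0,1) and sufficient-decrease
        constant of the line search.
    """

    newton_tol: float = 1e-10
    tol_mode: str = "relative"
    newton_atol: float | None = None
    max_newton_steps: int = 50
    inner_rtol: float = 1e-6
    inner_restart: int = 30
    inner_maxiter: int | None = 10  # restart cycles; caps matrix-free matvecs
    ls_shrink: float = 0.5
    ls_c: float = 1e-4
    max_backtracks: int = 30

    def __post_init__(self) -> None:
        if self.newton_tol <= 0 or self.inner_rtol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.ls_shrink < 1:
            raise ValueError("line-search shrink factor must lie in (0, 1)")
        if self.tol_mode not in ("relative", "absolute"):
            raise ValueError("tol_mode must be 'relative' or 'absolute'")


@dataclass
class NewtonReport:
    """Convergence history of one nonlinear solve."""

    newton_steps: int
    inner_iterations: list[int]
    residual_history: list[float]
    n_evals: int
    converged: bool
    message: str = ""


def default_perturbation(u: np.ndarray, v: np.ndarray) -> float:
    """Standard JFNK perturbation balancing truncation and round-off."""
    vnorm = np.linalg.norm(v)
    return np.sqrt(np.finfo(float).eps) * (1.0 + np.linalg.norm(u)) / vnorm


def jacobian_vector_product(
    HI,
    u: np.ndarray,
    v: np.ndarray,
    rule=default_perturbation,
    base_residual: np.ndarray | None = None,
) -> np.ndarray:
    """Finite-difference approximation of ``J(u) v``.

    ``base_residual`` may pass a cached ``HI(u)`` so only one new residual
    evaluation is spent; a zero direction returns zero without evaluating.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("direction vector must be finite")
    if not np.any(v):
        return np.zeros_like(v)
    rho = rule(u, v)
    if base_residual is None:
        base_residual = HI(u)
    return (HI(u + rho * v) - base_residual) / rho


def jfnk_solve(
    HI,
    u_init: np.ndarray,
    config: JFNKConfig | None = None,
    precond=None,
) -> tuple[np.ndarray, NewtonReport]:
    """Solve ``HI(u) = 0`` by Jacobian-free Newton-Krylov with line search.

    Parameters
    ----------
    HI : callable
        Residual operator on flat vectors; if it exposes ``n_evals`` the
        report records the number of evaluations spent.
    u_init : array
        Starting iterate (the previous scale step, in the segmentation
        driver).
    precond : LinearOperator, optional
        Preconditioner for the inner GMRES (e.g. an AMG V-cycle on a frozen
        linearization); unpreconditioned by default.
    """
    if config is None:
        config = JFNKConfig()
    u = np.asarray(u_init, dtype=float).copy()
    n = u.size
    evals0 = getattr(HI, "n_evals", 0)

    r = HI(u)
    rnorm = float(np.linalg.norm(r))
    history = [rnorm]
    inner_counts: list[int] = []
    atol = config.newton_atol
    if atol is None:
        atol = 100 * np.finfo(float).eps * np.sqrt(n)
    target = max(
        config.newton_tol * rnorm if config.tol_mode == "relative"
        else config.newton_tol,
        atol,
    )

    converged = rnorm <= target
    message = "converged at initial iterate" if converged else ""
    steps = 0
    while not converged and steps < config.max_newton_steps:
        base = r.copy()
        J = spla.LinearOperator(
            (n, n),
            matvec=lambda v: jacobian_vector_product(HI, u, v, base_residual=base),
        )
        delta, lin = gmres_solve(
            J, -r, precond=precond, rtol=config.inner_rtol,
            restart=config.inner_restart, maxiter=config.inner_maxiter,
        )
        inner_counts.append(lin.iterations)

        # backtracking line search: sufficient decrease of ||HI||
        lam = 1.0
        accepted = False
        for _ in range(config.max_backtracks + 1):
            trial = u + lam * delta
            r_trial = HI(trial)
            rn_trial = float(np.linalg.norm(r_trial))
            if rn_trial <= (1.0 - config.ls_c * lam) * rnorm:
                accepted = True
                break
            lam *= config.ls_shrink
        if not accepted:
            message = "line search failed to find sufficient decrease"
            break
        u, r, rnorm = trial, r_trial, rn_trial
        history.append(rnorm)
        steps += 1
        if rnorm <= target:
            converged = True
            message = "converged"

    if not converged and not message:
        message = "maximum Newton steps exceeded"
    report = NewtonReport(
        newton_steps=steps,
        inner_iterations=inner_counts,
        residual_history=history,
        n_evals=getattr(HI, "n_evals", evals0) - evals0,
        converged=converged,
        message=message,
    )
    return u, report
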