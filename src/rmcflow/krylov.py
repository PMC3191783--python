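"""Restarted GMRES with optional AMG preconditioning.

Thin wrapper over :func:`scipy.sparse.linalg.gmres` that counts inner
iterations, verifies the true (unpreconditioned) relative residual, and
returns a structured report.  The default tolerance ``1e-10`` is the
stopping criterion used for the per-step linear systems of the
semi-implicit algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla


@dataclass
class LinearSolveReport:
    """Outcome of one GMRES solve."""

    iterations: int
    relative_residual: float
    converged: bool
    levels: int | None = None  # AMG hierarchy depth, when preconditioned


def gmres_solve(
    A,
    b: np.ndarray,
    precond=None,
    rtol: float = 1e-10,
    restart: int = 30,
    maxiter: int | None = None,
    x0: np.ndarray | None = None,
    levels: int | None = None,
) -> tuple[np.ndarray, LinearSolveReport]:
    """Solve ``A x = b`` by restarted GMRES.

    Parameters
    ----------
    A : sparse matrix or LinearOperator
    precond : LinearOperator or None
        Applied as left preconditioner (e.g. one AMG V-cycle).
    rtol : float
        Target on the true relative residual ``||b - Ax|| / ||b||``.
    restart : int
        Krylov subspace size between restarts.
    levels : int, optional
        AMG depth recorded in the report for logging.
    """
    b = np.asarray(b, dtype=float)
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros_like(b), LinearSolveReport(0, 0.0, True, levels)

    count = {"k": 0}

    def cb(_pr_norm):
        count["k"] += 1

    if maxiter is None:
        maxiter = max(20, (b.size // max(restart, 1)) + 10)
    x, info = spla.gmres(
        A, b, x0=x0, rtol=rtol, atol=0.0, restart=restart, maxiter=maxiter,
        M=precond, callback=cb, callback_type="pr_norm",
    )
    rel = float(np.linalg.norm(b - A @ x) / bnorm)
    # left preconditioning monitors the preconditioned residual; polish if the
    # true residual is still above target
    polish = 0
    while info == 0 and rel > rtol and polish < 3:
        x, info = spla.gmres(
            A, b, x0=x, rtol=rtol * 1e-2, atol=rtol * bnorm, restart=restart,
            maxiter=maxiter, M=precond, callback=cb, callback_type="pr_norm",
        )
        rel = float(np.linalg.norm(b - A @ x) / bnorm)
        polish += 1
    report = LinearSolveReport(
        iterations=count["k"],
        relative_residual=rel,
        converged=(info == 0 and rel <= rtol),
        levels=levels,
    )
    return x, report
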