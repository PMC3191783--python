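"""Scale-stepping driver: schedule planning and the segmentation loop.

The evolution runs over a scale horizon ``T`` in steps of ``dtau``.  Matching
the temporal discretization error of the two engines exploits their orders:
the semi-implicit scheme is first order in ``dtau`` while Crank-Nicolson is
second order, so equal error budgets call for ``dtau_SI = dtau_I^2``.  The
driver executes ``ceil(T/dtau)`` steps of the chosen scheme, monitors the
scale-step residual ``||u_i - u_{i-1}|| / (dtau ||u_i||)`` for steady state,
and records per-step solver statistics.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .amg import AMGConfig, build_amg_hierarchy
from .discretize import (
    NonlinearResidualOperator,
    SegmentationState,
    assemble_si_system,
    assemble_spatial_operator,
    explicit_step,
)
from .edge import EdgeField, ModelParams, compute_edge_field
from .grid import GridSpec, grid_for_image
from .jfnk import JFNKConfig, NewtonReport, jfnk_solve
from .krylov import LinearSolveReport, gmres_solve
from .phantom import Phantom, make_seed_function

SCHEMES = ("explicit", "semi_implicit", "implicit")
STEADY_STATE_TOL = 1e-9
_RESIDUAL_FLOOR = 1e-30


def plan_step_sizes(dtau_implicit: float) -> tuple[float, float]:
    """Step sizes ``(dtau_SI, dtau_I)`` with matched discretization error.

    First order vs second order gives ``dtau_SI = dtau_I**2``; e.g.
    ``dtau_I = 0.4 -> dtau_SI = 0.16``.  Steps above 1 would grow under
    squaring, which defeats the matching, hence the warning.
    """
    if dtau_implicit <= 0:
        raise ValueError("dtau must be positive")
    if dtau_implicit > 1:
        warnings.warn(
            "dtau > 1: squaring enlarges the semi-implicit step", stacklevel=2
        )
    return dtau_implicit**2, dtau_implicit


def num_scale_steps(T: float, dtau: float) -> int:
    """Number of scale steps ``ceil(T / dtau)`` (e.g. T=0.4, dtau=0.16 -> 3).

    A tiny relative tolerance keeps exact divisions (0.4/0.04 -> 10) from
    rounding up through floating-point noise.
    """
    if T <= 0 or dtau <= 0:
        raise ValueError("T and dtau must be positive")
    return max(1, math.ceil(T / dtau - 1e-9))


@dataclass
class SchedulePlan:
    """Scheme choice plus scale schedule."""

    scheme: str
    dtau: float
    T: float
    n_steps: int | None = None
    target_order: float | None = None  # requested E_d magnitude, informational

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.dtau <= 0 or self.T <= 0:
            raise ValueError("dtau and T must be positive")
        if self.n_steps is None:
            self.n_steps = num_scale_steps(self.T, self.dtau)
        elif self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")


def steady_state_reached(
    u_curr: np.ndarray,
    u_prev: np.ndarray,
    dtau: float,
    tol: float = STEADY_STATE_TOL,
) -> tuple[bool, float]:
    """Scale-step residual test.

    Residual ``||u_curr - u_prev||_2 / (dtau * ||u_curr||_2 + floor)``;
    steady state is declared when it drops to ``tol`` (default 1e-9).
    """
    u_curr = np.asarray(u_curr, float)
    u_prev = np.asarray(u_prev, float)
    if u_curr.shape != u_prev.shape:
        raise ValueError("fields must share a grid")
    res = float(
        np.linalg.norm(u_curr - u_prev)
        / (dtau * np.linalg.norm(u_curr) + _RESIDUAL_FLOOR)
    )
    return res <= tol, res


@dataclass
class StepRecord:
    """Bookkeeping for one executed scale step."""

    step: int
    tau: float
    residual: float
    solver: Union[LinearSolveReport, NewtonReport, None]
    wall_time: float


@dataclass
class ConvergenceRecord:
    """Per-step history of a run; one entry per executed scale step."""

    scheme: str
    steps: list[StepRecord] = field(default_factory=list)
    stopped_early: bool = False
    failed: bool = False
    message: str = ""

    def __len__(self) -> int:
        return len(self.steps)

    def to_dicts(self) -> list[dict]:
        rows = []
        for s in self.steps:
            row = {
                "step": s.step,
                "tau": s.tau,
                "residual": s.residual,
                "wall_time": s.wall_time,
            }
            if isinstance(s.solver, LinearSolveReport):
                row["k_gmres"] = s.solver.iterations
                row["lv"] = s.solver.levels
            elif isinstance(s.solver, NewtonReport):
                row["n_newton"] = s.solver.newton_steps
                row["k_gmres"] = list(s.solver.inner_iterations)
            rows.append(row)
        return rows


def _implicit_substep(
    state: SegmentationState,
    edge: EdgeField,
    params: ModelParams,
    grid: GridSpec,
    dtau: float,
    theta: float,
    jfnk_config: JFNKConfig,
    amg_config: AMGConfig,
    precondition: bool,
) -> tuple[SegmentationState, NewtonReport]:
    """One nonlinear theta-step solved by JFNK."""
    op = NonlinearResidualOperator(state, edge, params, grid, dtau=dtau, theta=theta)
    precond = None
    if precondition:
        import scipy.sparse as sp

        A = assemble_spatial_operator(state.u, edge, params, grid)
        frozen = sp.identity(A.shape[0], format="csr") + theta * dtau * A
        precond = build_amg_hierarchy(frozen, amg_config).as_preconditioner()
    x, report = jfnk_solve(op, grid.pack(state.u), jfnk_config, precond=precond)
    new = SegmentationState(
        u=grid.unpack(x), scale_index=state.scale_index, tau=state.tau + dtau
    )
    return new, report


def _merge_reports(a: NewtonReport, b: NewtonReport) -> NewtonReport:
    """Combine the reports of two half-steps into one scale-step record."""
    return NewtonReport(
        newton_steps=a.newton_steps + b.newton_steps,
        inner_iterations=a.inner_iterations + b.inner_iterations,
        residual_history=a.residual_history + b.residual_history,
        n_evals=a.n_evals + b.n_evals,
        converged=a.converged and b.converged,
        message=b.message or a.message,
    )


def run_segmentation(
    image_or_phantom,
    params: ModelParams,
    plan: SchedulePlan,
    *,
    u0: np.ndarray | None = None,
    seed_center: tuple[float, float] = (0.5, 0.5),
    seed_radius: float = 0.15,
    edge: EdgeField | None = None,
    amg_config: AMGConfig | None = None,
    jfnk_config: JFNKConfig | None = None,
    linear_rtol: float = 1e-10,
    gmres_restart: int = 30,
    steady_tol: float = STEADY_STATE_TOL,
    early_stop: bool = True,
    precondition_jfnk: bool = True,
    implicit_startup: int = 1,
) -> tuple[SegmentationState, ConvergenceRecord]:
    """Run the chosen scheme over the scale schedule.

    Parameters
    ----------
    image_or_phantom : 2D array or Phantom
        Image to segment, intensities in [0, 1].
    u0 : array, optional
        Initial segmentation function; built from the seed circle
        (``seed_center``, ``seed_radius``) when omitted.
    precondition_jfnk : bool
        Precondition the inner Krylov solves of the implicit path with an
        AMG V-cycle on the frozen linearization ``I + theta*dtau A(u_prev)``.
    implicit_startup : int
        Number of leading implicit steps replaced by two L-stable backward
        Euler half-steps (Rannacher startup).  Crank-Nicolson barely damps
        stiff components of the initial seed function (its amplification
        factor tends to -1), so without this the slowly decaying remnant of
        the seed eventually dominates the decaying solution; one damped step
        removes it while preserving second-order accuracy in ``dtau``.

    Returns the final state and the full convergence record; an inner-solver
    failure aborts with the partial record flagged as failed.
    """
    if isinstance(image_or_phantom, Phantom):
        image = image_or_phantom.image
        grid = image_or_phantom.grid
    else:
        image = np.asarray(image_or_phantom, dtype=float)
        grid = grid_for_image(image)
    if edge is None:
        edge = compute_edge_field(image, params, grid)
    if u0 is None:
        u0 = make_seed_function(grid, seed_center, seed_radius)
    if amg_config is None:
        amg_config = AMGConfig()
    if jfnk_config is None:
        jfnk_config = JFNKConfig()

    state = SegmentationState(u=np.asarray(u0, float), scale_index=0, tau=0.0)
    record = ConvergenceRecord(scheme=plan.scheme)
    dtau = plan.dtau

    for i in range(1, plan.n_steps + 1):
        t0 = time.perf_counter()
        solver_report: Union[LinearSolveReport, NewtonReport, None] = None
        if plan.scheme == "explicit":
            new_state = explicit_step(state, edge, params, grid, dtau=dtau)
        elif plan.scheme == "semi_implicit":
            system = assemble_si_system(state, edge, params, grid, dtau=dtau)
            hierarchy = build_amg_hierarchy(system.matrix, amg_config)
            x, solver_report = gmres_solve(
                system.matrix,
                system.rhs,
                precond=hierarchy.as_preconditioner(),
                rtol=linear_rtol,
                restart=gmres_restart,
                x0=grid.pack(state.u),
                levels=hierarchy.depth,
            )
            if not solver_report.converged:
                record.failed = True
                record.message = f"GMRES failed at scale step {i}"
                break
            new_state = SegmentationState(
                u=grid.unpack(x), scale_index=i, tau=state.tau + dtau
            )
        else:  # implicit
            if i <= implicit_startup:
                substeps = [(dtau / 2, 1.0), (dtau / 2, 1.0)]
            else:
                substeps = [(dtau, 0.5)]
            work = state
            solver_report = None
            for dt_sub, theta in substeps:
                sub_report = _implicit_substep(
                    work, edge, params, grid, dt_sub, theta,
                    jfnk_config, amg_config, precondition_jfnk,
                )
                work, rep = sub_report
                solver_report = (
                    rep if solver_report is None else _merge_reports(solver_report, rep)
                )
                if not rep.converged:
                    break
            if not solver_report.converged:
                record.failed = True
                record.message = (
                    f"JFNK failed at scale step {i}: {solver_report.message}"
                )
                break
            new_state = SegmentationState(
                u=work.u, scale_index=i, tau=state.tau + dtau
            )

        reached, res = steady_state_reached(new_state.u, state.u, dtau, steady_tol)
        record.steps.append(
            StepRecord(
                step=i,
                tau=new_state.tau,
                residual=res,
                solver=solver_report,
                wall_time=time.perf_counter() - t0,
            )
        )
        state = new_state
        if early_stop and reached:
            record.stopped_early = True
            break

    return state, record
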