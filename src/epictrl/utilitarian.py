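"""Utilitarian (fully coordinated) optimum of the population utility.

Identical sweep machinery to the Nash solver, but the costate for the
infected fraction carries the infection externality a self-interested
individual ignores:

    v_i' = f^(−t)[α(i) + α'(i) i] + (v_s − v_i) k s + v_i.

The extra (v_s − v_i) k s term prices the onward infections each case causes;
the α'(i) i term prices the congestion externality of pushing the healthcare
system towards its threshold. The control rule is the same as the Nash one,
so the two solutions differ only through the costates.

With a steep healthcare-threshold cost the coordinated problem develops a
"threshold-tracking" optimum whose damped sweep map is violently unstable
(the α'(i) term acts like a stiff penalty), so the solver escalates through
three engines: damped sweep, Anderson-accelerated polish, and finally a
direct-transcription search followed by a Newton collocation solve of the
optimality boundary-value problem.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.integrate import solve_bvp

from . import _kernels
from .costs import (
    evaluate_objective,
    infection_cost,
    infection_cost_derivative,
)
from .epidemic import BURNOUT_THRESHOLD, integrate_sir
from .grid import TimeGrid
from .nash import control_update, terminal_costates, _cost_scalars, _default_tol
from .params import ModelParams, UtilityParams
from .sweep import SweepOptions, anderson_fixed_point, damped_fixed_point
from .trajectory import CostateTrajectory, Solution, Trajectory

__all__ = ["population_costates", "solve_utilitarian", "solve_utilitarian_bvp"]

logger = logging.getLogger(__name__)


def population_costates(traj: Trajectory, up: UtilityParams) -> CostateTrajectory:
    """Backward integration of the coordinated problem's Lagrange multipliers."""
    grid = traj.grid
    vs_T, vi_T = terminal_costates(up, grid.tf)
    v_s, v_i = _kernels.costates_backward(
        traj.k, traj.s, traj.i, grid.dt, grid.t0, up.log_f,
        *_cost_scalars(up.cost), vs_T, vi_T, True,
    )
    return CostateTrajectory(grid=grid, v_s=v_s, v_i=v_i)


def solve_utilitarian_bvp(
    params: ModelParams,
    grid: TimeGrid,
    eps_path: np.ndarray | None = None,
    init_k: np.ndarray | None = None,
    bvp_tol: float = 1e-9,
) -> Solution:
    """Coordinated optimum by Newton collocation on the optimality BVP.

    Four states (s, i, v_s, v_i) with the control eliminated through the
    pointwise rule; the population costate dynamics carry the α'(i) i and
    (v_s − v_i) k s externality terms. The collocation solution is projected
    back onto the shared grid (k at the nodes, then one forward/backward
    fixed-step pass), and the reported residual is the discrete consistency
    gap of that projection.
    """
    from scipy.interpolate import CubicSpline

    eps = np.zeros(grid.n) if eps_path is None else np.asarray(eps_path, float)
    ep, up = params.epidemic, params.utility
    lnf, beta, kstar = up.log_f, up.beta, ep.kappa_star
    nodes = grid.nodes
    vs_T, vi_T = terminal_costates(up, grid.tf)
    e_spline = CubicSpline(nodes, eps)

    def rhs(t, y):
        s, i, vs, vi = y
        ft = np.exp(t * lnf)
        k = np.maximum(
            kstar - 0.5 * ft * (vs - vi) * s * i / beta
            + 0.5 * e_spline(t) / beta,
            0.0,
        )
        disc = np.exp(-t * lnf)
        a = infection_cost(i, up.cost)
        ap = infection_cost_derivative(i, up.cost)
        return np.vstack(
            [
                -k * s * i,
                k * s * i - i,
                (vs - vi) * k * i,
                disc * (a + ap * i) + (vs - vi) * k * s + vi,
            ]
        )

    def bc(ya, yb):
        return np.array([ya[0] - ep.s0, ya[1] - ep.i0, yb[2], yb[3] - vi_T])

    k0 = np.full(grid.n, kstar) if init_k is None else np.asarray(init_k, float)
    traj0 = integrate_sir(k0, ep, grid, eps_path=eps)
    cs0 = population_costates(traj0, up)
    stride = max(1, (grid.n - 1) // 1000)
    mesh = nodes[::stride]
    if mesh[-1] != nodes[-1]:
        mesh = np.append(mesh, nodes[-1])
    y0 = np.vstack(
        [
            np.interp(mesh, nodes, traj0.s),
            np.interp(mesh, nodes, traj0.i),
            np.interp(mesh, nodes, cs0.v_s),
            np.interp(mesh, nodes, cs0.v_i),
        ]
    )
    with np.errstate(over="ignore", invalid="ignore"):
        # Newton trial iterates may transiently overflow; harmless
        bvp = solve_bvp(rhs, bc, mesh, y0, tol=bvp_tol, max_nodes=40_000)
    if not bvp.success:
        logger.warning("coordinated BVP solve: %s", bvp.message)
    y = bvp.sol(nodes)
    ft = np.exp(nodes * lnf)
    k = np.maximum(
        kstar - 0.5 * ft * (y[2] - y[3]) * y[0] * y[1] / beta + 0.5 * eps / beta,
        0.0,
    )
    traj = integrate_sir(k, ep, grid, eps_path=eps)
    costates = population_costates(traj, up)
    cand = control_update(traj, costates, eps, up)
    return Solution(
        traj=traj,
        costates=costates,
        objective=evaluate_objective(traj, "population", up, params.government),
        converged=bool(bvp.success),
        iterations=int(getattr(bvp, "niter", 0)),
        residual=float(np.max(np.abs(cand - k))),
        method="collocation",
    )


def _sweep_step_factory(params, grid, eps):
    ep, up = params.epidemic, params.utility

    def step(k):
        traj = integrate_sir(np.maximum(k, 0.0), ep, grid, eps_path=eps)
        costates = population_costates(traj, up)
        cand = control_update(traj, costates, eps, up)
        return cand, (traj, costates)

    return step


def _transcription_init(params, grid, eps):
    # imported lazily: validation depends on nash, not on this module
    from .validation import TranscriptionSpec, direct_transcription_optimize

    tr = direct_transcription_optimize(
        TranscriptionSpec(objective_kind="population", n_nodes=60, n_restarts=3),
        params,
        grid,
        fixed_eps=eps,
        seed=1,
    )
    return tr.control


def solve_utilitarian(
    params: ModelParams,
    grid: TimeGrid | None = None,
    eps_path: np.ndarray | None = None,
    opts: SweepOptions | None = None,
    init_k: np.ndarray | None = None,
    auto_extend: bool = True,
    max_extensions: int = 3,
) -> Solution:
    """Coordinated optimum of U_p.

    Engine escalation: (1) damped forward-backward sweep; (2) Anderson
    polish from the sweep's last iterate; (3) direct-transcription search of
    the objective followed by a Newton collocation solve of the optimality
    system, warm-started from the transcription optimum, with a final
    Anderson polish attempt on the discrete map. Threshold-tracking optima
    (steep α near i_hc) typically end at stage (3); the returned Solution's
    ``method``/``converged``/``residual`` say which engine produced it and
    how consistent it is on the fixed grid.
    """
    grid = grid or TimeGrid()
    opts = opts or SweepOptions()
    ep, up = params.epidemic, params.utility
    tol = _default_tol(opts, ep.kappa_star)

    for attempt in range(max_extensions + 1):
        eps = np.zeros(grid.n) if eps_path is None else np.asarray(eps_path, float)
        if eps.shape != (grid.n,):
            raise ValueError(f"eps_path must have shape ({grid.n},)")
        k0 = np.full(grid.n, ep.kappa_star) if init_k is None else np.asarray(init_k, float)
        step = _sweep_step_factory(params, grid, eps)

        res = damped_fixed_point(step, k0, tol, opts, label="utilitarian")
        method = "sweep"
        if not res.converged:
            res2 = anderson_fixed_point(
                step, res.x, tol, SweepOptions(
                    relaxation=0.02, max_iter=300, patience=30,
                    anderson_window=opts.anderson_window,
                ),
                label="utilitarian-anderson", mixing=0.25, lower_bound=0.0,
            )
            if res2.residual < res.residual:
                res = res2
        if not res.converged:
            logger.info("utilitarian sweep stalled; trying transcription + collocation")
            k_tr = _transcription_init(params, grid, eps)
            sol_bvp = solve_utilitarian_bvp(
                params, grid, eps_path=eps, init_k=k_tr
            )
            polish = anderson_fixed_point(
                step, sol_bvp.traj.k, tol, SweepOptions(
                    relaxation=0.01, max_iter=150, patience=20,
                    anderson_window=6,
                ),
                label="utilitarian-polish", mixing=0.25, lower_bound=0.0,
            )
            if polish.converged:
                res = polish
                method = "sweep"
            else:
                sweep_obj = (
                    evaluate_objective(res.aux[0], "population", up, params.government)
                    if res.aux is not None
                    else -np.inf
                )
                if sol_bvp.objective >= sweep_obj:
                    sol = sol_bvp
                    if auto_extend and sol.traj.i[-1] > BURNOUT_THRESHOLD and attempt < max_extensions:
                        new_grid = grid.extended()
                        logger.info(
                            "i(tf)=%.2e: extending horizon %.4g -> %.4g",
                            sol.traj.i[-1], grid.tf, new_grid.tf,
                        )
                        init_k = np.interp(
                            new_grid.nodes, grid.nodes, sol.traj.k,
                            right=ep.kappa_star,
                        )
                        if eps_path is not None:
                            eps_path = np.interp(
                                new_grid.nodes, grid.nodes, eps, right=0.0
                            )
                        grid = new_grid
                        continue
                    return sol
                # the stalled sweep iterate is, by objective, the better point
                method = "sweep"

        traj, costates = res.aux
        if not auto_extend or traj.i[-1] <= BURNOUT_THRESHOLD or attempt == max_extensions:
            break
        new_grid = grid.extended()
        logger.info(
            "i(tf)=%.2e: extending horizon %.4g -> %.4g", traj.i[-1], grid.tf, new_grid.tf
        )
        pad = new_grid.n - grid.n
        init_k = np.concatenate([res.x, np.full(pad, ep.kappa_star)])
        if eps_path is not None:
            eps_path = np.concatenate([eps, np.zeros(pad)])
        grid = new_grid

    objective = evaluate_objective(traj, "population", up, params.government)
    return Solution(
        traj=traj,
        costates=costates,
        objective=objective,
        converged=res.converged,
        iterations=res.iterations,
        residual=res.residual,
        method=method,
    )
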