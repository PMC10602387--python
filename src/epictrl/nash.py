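"""Nash-equilibrium social distancing via forward-backward sweep.

A representative individual chooses their own infectiousness κ(t) to maximise
discounted utility against the population epidemic, which they cannot
influence. Pontryagin's principle turns that control problem into costate
equations for the marginal values v_s, v_i of being susceptible/infectious,

    v_s' = (v_s − v_i) κ i,        v_s(tf) = 0,
    v_i' = f^(−t) α(i) + v_i,      v_i(tf) = −f^(−tf) α(0)/(1 + ln f),

and the interior optimality condition

    κ = κ* − f^t/2 · (v_s − v_i) ψ_s i + ε/2,   clipped at κ ≥ 0.

The Nash equilibrium is the self-consistent point where the population adopts
the individual best response (k = κ, s = ψ_s, i = ψ_i). It is computed by
iterating forward SIR integration, backward costate integration, and a damped
control update.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.integrate import solve_bvp
from scipy.interpolate import CubicSpline

from . import _kernels
from .costs import evaluate_objective, infection_cost, salvage_individual
from .epidemic import BURNOUT_THRESHOLD, integrate_sir
from .grid import TimeGrid
from .params import InfectionCostParams, ModelParams, UtilityParams
from .sweep import SweepOptions, damped_fixed_point
from .trajectory import CostateTrajectory, Solution, Trajectory

__all__ = [
    "individual_costates",
    "control_update",
    "solve_nash",
    "solve_nash_bvp",
    "best_response",
    "individual_objective",
    "terminal_costates",
]

logger = logging.getLogger(__name__)


def _cost_scalars(p: InfectionCostParams) -> tuple:
    return (p.alpha0, p.alpha1, p.i_hc, p.sigma, p.constant)


def terminal_costates(up: UtilityParams, tf: float) -> tuple[float, float]:
    """(v_s(tf), v_i(tf)) from the salvage term's state derivatives."""
    lnf = up.log_f
    vi_T = -math.exp(-tf * lnf) * up.cost.alpha_at_zero() / (1.0 + lnf)
    return 0.0, vi_T


def individual_costates(traj: Trajectory, up: UtilityParams) -> CostateTrajectory:
    """Backward costate integration along an equilibrium trajectory (κ = k)."""
    grid = traj.grid
    vs_T, vi_T = terminal_costates(up, grid.tf)
    v_s, v_i = _kernels.costates_backward(
        traj.k, traj.s, traj.i, grid.dt, grid.t0, up.log_f,
        *_cost_scalars(up.cost), vs_T, vi_T, False,
    )
    return CostateTrajectory(grid=grid, v_s=v_s, v_i=v_i)


def control_update(
    traj: Trajectory,
    costates: CostateTrajectory,
    eps_path: np.ndarray,
    up: UtilityParams,
    psi_s: np.ndarray | None = None,
) -> np.ndarray:
    """Pointwise optimal behaviour κ* − f^t/2·(v_s−v_i)·ψ_s·i + ε/2, clipped ≥ 0.

    At equilibrium ψ_s is the population susceptible path (default); for a
    best-response computation pass the individual's own ψ_s.
    """
    if not traj.grid.same_as(costates.grid):
        raise ValueError("trajectory and costates live on different grids")
    ps = traj.s if psi_s is None else psi_s
    ft = np.exp(traj.grid.nodes * up.log_f)
    cand = (
        traj.kappa_star
        - 0.5 * ft * (costates.v_s - costates.v_i) * ps * traj.i / up.beta
        + 0.5 * eps_path / up.beta
    )
    return np.maximum(cand, 0.0)


def _default_tol(opts: SweepOptions, kappa_star: float) -> float:
    return opts.tol if opts.tol is not None else 1e-6 * kappa_star


def solve_nash(
    params: ModelParams,
    grid: TimeGrid | None = None,
    eps_path: np.ndarray | None = None,
    opts: SweepOptions | None = None,
    init_k: np.ndarray | None = None,
    auto_extend: bool = True,
    max_extensions: int = 3,
) -> Solution:
    """Equilibrium behaviour under an exogenous intervention field ε.

    Sweep: initialise k ≡ κ*; iterate {forward SIR; backward costates;
    clipped control update; damped mixing} until the unrelaxed control
    residual drops below tol. If the epidemic has not burnt out by tf
    (i(tf) > 1e-8) and ``auto_extend`` is set, the horizon is stretched by
    50% (ε padded with zeros, warm-started) and the solve repeated.
    """
    grid = grid or TimeGrid()
    opts = opts or SweepOptions()
    ep, up = params.epidemic, params.utility
    for attempt in range(max_extensions + 1):
        eps = np.zeros(grid.n) if eps_path is None else np.asarray(eps_path, float)
        if eps.shape != (grid.n,):
            raise ValueError(f"eps_path must have shape ({grid.n},)")
        k0 = np.full(grid.n, ep.kappa_star) if init_k is None else np.asarray(init_k, float)

        def step(k):
            traj = integrate_sir(k, ep, grid, eps_path=eps)
            costates = individual_costates(traj, up)
            cand = control_update(traj, costates, eps, up)
            return cand, (traj, costates)

        res = damped_fixed_point(
            step, k0, _default_tol(opts, ep.kappa_star), opts, label="nash"
        )
        traj, costates = res.aux
        if not auto_extend or traj.i[-1] <= BURNOUT_THRESHOLD or attempt == max_extensions:
            break
        new_grid = grid.extended()
        logger.info(
            "i(tf)=%.2e > %.0e: extending horizon %.4g -> %.4g",
            traj.i[-1], BURNOUT_THRESHOLD, grid.tf, new_grid.tf,
        )
        pad = new_grid.n - grid.n
        init_k = np.concatenate([res.x, np.full(pad, ep.kappa_star)])
        if eps_path is not None:
            eps_path = np.concatenate([eps, np.zeros(pad)])
        grid = new_grid
    objective = evaluate_objective(traj, "individual", up, params.government)
    return Solution(
        traj=traj,
        costates=costates,
        objective=objective,
        converged=res.converged,
        iterations=res.iterations,
        residual=res.residual,
    )


def solve_nash_bvp(
    params: ModelParams,
    grid: TimeGrid,
    eps_path: np.ndarray | None = None,
    init_k: np.ndarray | None = None,
    bvp_tol: float = 1e-9,
) -> Solution:
    """Equilibrium by Newton collocation on the self-consistent BVP.

    The equilibrium conditions form a four-state two-point boundary value
    problem in (s, i, v_s, v_i) once the behaviour is eliminated through the
    pointwise rule k = max(0, κ* − f^t/2 (v_s − v_i) s i + ε/2). Solved with
    a damped-Newton collocation method — slower per call than a sweep
    iteration but immune to the oscillatory modes that can defeat the damped
    fixed-point iteration for some intervention fields. The collocation
    result is projected back onto the shared grid (k at the nodes, then one
    forward/backward pass of the fixed-step scheme) so downstream consumers
    see the same discretization as the sweep solver.
    """
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
        return np.vstack(
            [
                -k * s * i,
                k * s * i - i,
                (vs - vi) * k * i,
                disc * infection_cost(i, up.cost) + vi,
            ]
        )

    def bc(ya, yb):
        return np.array([ya[0] - ep.s0, ya[1] - ep.i0, yb[2], yb[3] - vi_T])

    k0 = np.full(grid.n, kstar) if init_k is None else np.asarray(init_k, float)
    traj0 = integrate_sir(k0, ep, grid, eps_path=eps)
    cs0 = individual_costates(traj0, up)
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
        bvp = solve_bvp(rhs, bc, mesh, y0, tol=bvp_tol, max_nodes=60_000)
    if not bvp.success:
        logger.warning("equilibrium BVP solve: %s", bvp.message)
    y = bvp.sol(nodes)
    ft = np.exp(nodes * lnf)
    k = np.maximum(
        kstar - 0.5 * ft * (y[2] - y[3]) * y[0] * y[1] / beta + 0.5 * eps / beta,
        0.0,
    )
    traj = integrate_sir(k, ep, grid, eps_path=eps)
    costates = individual_costates(traj, up)
    cand = control_update(traj, costates, eps, up)
    residual = float(np.max(np.abs(cand - k)))
    objective = evaluate_objective(traj, "individual", up, params.government)
    return Solution(
        traj=traj,
        costates=costates,
        objective=objective,
        converged=bool(bvp.success),
        iterations=int(bvp.niter) if hasattr(bvp, "niter") else 0,
        residual=residual,
        method="collocation",
    )


def individual_objective(
    kappa: np.ndarray,
    psi_s: np.ndarray,
    psi_i: np.ndarray,
    pop: Trajectory,
    up: UtilityParams,
) -> float:
    """Utility of an individual playing κ against the frozen population.

    ∫ f^(−t)[−α(i)ψ_i − β(κ−κ*)² + (κ−κ*)ε] dt plus the ψ_i salvage term;
    α is evaluated at the *population* infected fraction.
    """
    t = pop.grid.nodes
    disc = np.exp(-t * up.log_f)
    dk = kappa - pop.kappa_star
    integrand = disc * (
        -infection_cost(pop.i, up.cost) * psi_i - up.beta * dk**2 + dk * pop.eps
    )
    tail = salvage_individual(float(psi_i[-1]), up.f, pop.grid.tf, up.cost)
    return float(np.trapezoid(integrand, dx=pop.grid.dt) + tail)


def best_response(
    k_path: np.ndarray,
    params: ModelParams,
    grid: TimeGrid | None = None,
    eps_path: np.ndarray | None = None,
    opts: SweepOptions | None = None,
    init_kappa: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Stationary individual behaviour κ against a fixed population behaviour.

    The population trajectory from ``k_path`` is computed once and frozen,
    and the individual's Pontryagin boundary-value problem in
    (ψ_s, ψ_i, v_s, v_i) — with the control eliminated through the pointwise
    optimality rule — is solved by Newton-based collocation. Returns
    (κ, individual utility). Used to verify the Nash fixed-point property:
    at equilibrium, κ reproduces ``k_path``.

    The Newton iteration starts from ``init_kappa`` (default: the population
    strategy itself, i.e. the would-be defector starts at consensus). The
    individual's problem is not concave — the bilinear infection dynamics
    admit, besides the cautious consensus point, a second "give-up"
    stationary strategy with little distancing and early infection — so the
    start selects which stationary point is found; pass κ* ≡ const to probe
    the reckless branch. ``opts`` is accepted for interface symmetry with the
    sweep solvers and currently unused.
    """
    grid = grid or TimeGrid()
    ep, up = params.epidemic, params.utility
    eps = np.zeros(grid.n) if eps_path is None else np.asarray(eps_path, float)
    pop = integrate_sir(np.asarray(k_path, float), ep, grid, eps_path=eps)
    vs_T, vi_T = terminal_costates(up, grid.tf)
    cs = _cost_scalars(up.cost)
    nodes = grid.nodes
    lnf, beta, kstar = up.log_f, up.beta, ep.kappa_star

    # Picard/damped iteration on the frozen-population optimality system is
    # linearly unstable at the consensus solution (a less cautious κ lowers
    # ψ_s, which rewards even less caution — the feedback that also creates
    # the second, "give-up" stationary point), so the two-point boundary
    # value problem is solved with a Newton-based collocation method, which
    # converges to the stationary point nearest the initial guess.
    # smooth interpolants of the frozen exogenous paths keep the collocation
    # residual from being floored by interpolation error
    i_spline = CubicSpline(nodes, pop.i)
    e_spline = CubicSpline(nodes, eps)

    def kappa_rule(t, ps, vs, vi):
        ft = np.exp(t * lnf)
        i_ = i_spline(t)
        e_ = e_spline(t)
        return np.maximum(
            kstar - 0.5 * ft * (vs - vi) * ps * i_ / beta + 0.5 * e_ / beta, 0.0
        )

    def rhs(t, y):
        ps, _pi, vs, vi = y
        i_ = i_spline(t)
        kap = kappa_rule(t, ps, vs, vi)
        disc = np.exp(-t * lnf)
        return np.vstack(
            [
                -kap * ps * i_,
                kap * ps * i_ - _pi,
                (vs - vi) * kap * i_,
                disc * infection_cost(i_, up.cost) + vi,
            ]
        )

    def bc(ya, yb):
        return np.array([ya[0] - ep.s0, ya[1] - ep.i0, yb[2], yb[3] - vi_T])

    kappa0 = (
        np.array(pop.k, dtype=float)
        if init_kappa is None
        else np.asarray(init_kappa, float)
    )
    ps0, pi0 = _kernels.psi_forward(kappa0, pop.i, ep.s0, ep.i0, grid.dt)
    vs0, vi0 = _kernels.costates_backward(
        kappa0, pop.s, pop.i, grid.dt, grid.t0, lnf, *cs, vs_T, vi_T, False
    )
    stride = max(1, (grid.n - 1) // 1000)
    mesh = nodes[::stride]
    if mesh[-1] != nodes[-1]:
        mesh = np.append(mesh, nodes[-1])
    y0 = np.vstack([
        np.interp(mesh, nodes, ps0),
        np.interp(mesh, nodes, pi0),
        np.interp(mesh, nodes, vs0),
        np.interp(mesh, nodes, vi0),
    ])
    with np.errstate(over="ignore", invalid="ignore"):
        # Newton trial iterates may transiently overflow; harmless
        bvp = solve_bvp(rhs, bc, mesh, y0, tol=1e-8, max_nodes=60_000)
    if not bvp.success:
        logger.warning("best_response BVP solve failed: %s", bvp.message)
    y = bvp.sol(nodes)
    ps, pi = y[0], y[1]
    kappa = kappa_rule(nodes, y[0], y[2], y[3])
    return kappa, individual_objective(kappa, ps, pi, pop, up)
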