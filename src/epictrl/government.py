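"""Nested optimisation of a costly government intervention field ε(t).

The government leads, the population follows: for any intervention path ε the
population settles into the Nash equilibrium k(ε), and the government chooses
ε to maximise its own discounted objective V, which prices infections (α_g,
with its own healthcare-threshold step), deviations of behaviour from
baseline (β_g), and the intervention process itself (γ_g, the shadow cost of
public funds). Pontryagin's principle applied to the reduced problem gives
government costates λ_s, λ_i driven by the auxiliary integrand Λ, and the
interior optimality condition

    ε = i s [f^t (β_g + γ_g)(v_s − v_i) − f_g^t (λ_s − λ_i)] / (β_g + 2 γ_g),

where (v_s, v_i) are the *inner* equilibrium's costates. The solver is an
outer damped sweep over ε whose forward pass is itself a full Nash sweep
(warm-started between outer iterations).

With a healthcare threshold in α_g the government objective is non-convex and
two local optima coexist near a critical maximum infection cost: a
"high-peak" policy tolerating a large outbreak, and a "threshold-tracking"
policy pinning infections near i_hc. ``branch_scan`` follows both branches by
continuation in α_g1 and selects the global optimum, locating the
discontinuous policy switch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np

from . import _kernels
from .costs import evaluate_objective, infection_cost, infection_cost_derivative
from .epidemic import BURNOUT_THRESHOLD
from .grid import TimeGrid
from .nash import solve_nash, solve_nash_bvp, _cost_scalars
from .params import GovernmentParams, ModelParams, UtilityParams
from .sweep import SweepOptions, anderson_fixed_point
from .trajectory import (
    CostateTrajectory,
    GovernmentCostates,
    GovernmentSolution,
    Solution,
    Trajectory,
)

__all__ = [
    "government_costates",
    "epsilon_update",
    "decentralization_ansatz",
    "solve_government",
    "branch_scan",
    "find_switch",
]

logger = logging.getLogger(__name__)

#: sup-norm ε distance below which two converged optima count as the same.
DISTINCT_OPTIMA_TOL = 1e-2


def government_costates(
    traj: Trajectory,
    inner_costates: CostateTrajectory,
    gp: GovernmentParams,
    up: UtilityParams,
) -> GovernmentCostates:
    """Backward integration of λ_s, λ_i along a converged inner equilibrium."""
    grid = traj.grid
    if not grid.same_as(inner_costates.grid):
        raise ValueError("trajectory and inner costates live on different grids")
    lnfg = gp.log_f_g
    li_T = -math.exp(-grid.tf * lnfg) * gp.cost_g.alpha_at_zero() / (1.0 + lnfg)
    ls, li, lam = _kernels.gov_costates_backward(
        traj.s, traj.i, traj.eps, inner_costates.v_s, inner_costates.v_i,
        grid.dt, grid.t0, up.log_f, lnfg, traj.kappa_star,
        gp.beta_g, gp.gamma_g, *_cost_scalars(gp.cost_g), 0.0, li_T,
    )
    return GovernmentCostates(grid=grid, lambda_s=ls, lambda_i=li, Lambda=lam)


def epsilon_update(
    traj: Trajectory,
    inner_costates: CostateTrajectory,
    gov_costates: GovernmentCostates,
    gp: GovernmentParams,
    up: UtilityParams,
) -> np.ndarray:
    """Pointwise stationary intervention from the government Hamiltonian."""
    denom = gp.beta_g + 2.0 * gp.gamma_g
    if denom == 0.0:
        raise ValueError("beta_g + 2*gamma_g must be positive")
    if not traj.grid.same_as(gov_costates.grid):
        raise ValueError("trajectory and government costates live on different grids")
    t = traj.grid.nodes
    ft = np.exp(t * up.log_f)
    fgt = np.exp(t * gp.log_f_g)
    return (
        traj.i
        * traj.s
        * (
            ft * (gp.beta_g + gp.gamma_g) * (inner_costates.v_s - inner_costates.v_i)
            - fgt * (gov_costates.lambda_s - gov_costates.lambda_i)
        )
        / denom
    )


def decentralization_ansatz(
    params: ModelParams,
    grid: TimeGrid,
    opts: SweepOptions | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Intervention field that decentralizes the government's preferred path.

    Solves the coordinated (utilitarian) problem under the *government's*
    preferences (f_g, α_g, β_g), then chooses ε so that the individual
    optimality rule reproduces that behaviour:

        ε = 2β (k_g − κ*) + f^t (v_s − v_i) s i,

    with (v_s, v_i) the individual's costates along the government-preferred
    trajectory. Returns ``(ε, k_g)``. For cost-free intervention (γ_g = 0)
    this is the optimum itself (the government can steer the population
    exactly); for γ_g > 0 it is the natural warm start for the outer sweep.

    The accompanying behaviour path matters: a strongly activity-subsidising
    ε supports *several* population equilibria (the intended calm one and a
    reckless, fierce-epidemic one), and the inner solver's warm start selects
    among them. Starting the outer sweep from (ε, k_g) keeps every inner
    solve in the calm basin, whereas a cold ε ≡ 0 start can wander through
    intervention fields where the calm equilibrium is unstable.
    """
    from .nash import individual_costates
    from .utilitarian import solve_utilitarian

    gp, up, ep = params.government, params.utility, params.epidemic
    gov_pref = UtilityParams(f=gp.f_g, beta=gp.beta_g, cost=gp.cost_g)
    target = solve_utilitarian(
        ModelParams(epidemic=ep, utility=gov_pref),
        grid,
        opts=opts,
        auto_extend=False,
    )
    if not target.converged:
        logger.warning(
            "government-preference coordinated solve did not fully converge "
            "(residual %.3e); ansatz may be rough", target.residual
        )
    v = individual_costates(target.traj, up)
    ft = np.exp(grid.nodes * up.log_f)
    eps = (
        2.0 * up.beta * (target.traj.k - ep.kappa_star)
        + ft * (v.v_s - v.v_i) * target.traj.s * target.traj.i
    )
    return eps, target.traj.k.copy()


def _branch_label(sol: Solution, gp: GovernmentParams) -> str:
    if gp.cost_g.constant:
        return "high-peak"
    peak = float(sol.traj.i.max())
    return "threshold-tracking" if peak < 2.0 * gp.cost_g.i_hc else "high-peak"


def solve_government(
    params: ModelParams,
    grid: TimeGrid | None = None,
    opts_inner: SweepOptions | None = None,
    opts_outer: SweepOptions | None = None,
    init_eps: np.ndarray | None = None,
    auto_extend: bool = True,
    max_extensions: int = 3,
) -> GovernmentSolution:
    """Optimal intervention by nested forward-backward sweep.

    Each outer iteration re-equilibrates the population: the current ε is fed
    to a full Nash solve (warm-started from the previous outer iterate), the
    government costates are integrated backward along the result, and ε is
    updated towards the stationary rule. The outer fixed point is driven by
    Anderson acceleration with damped safeguards (the plain damped outer map
    is stable only under impractically heavy damping). Threshold-tracking
    optima whose discrete outer map cannot be iterated at all fall back to a
    Newton collocation solve of the six-state government optimality system.
    By default the outer field starts from the decentralization ansatz and
    the inner solver from its companion behaviour path.
    """
    if params.government is None:
        raise ValueError("params.government is required")
    grid = grid or TimeGrid()
    gp, up, ep = params.government, params.utility, params.epidemic
    # the inner equilibrium is solved tighter than the outer field so that
    # inner error does not floor the outer residual
    opts_inner = opts_inner or SweepOptions(tol=1e-7 * ep.kappa_star, max_iter=3000)
    opts_outer = opts_outer or SweepOptions(
        relaxation=0.05, max_iter=500, patience=30
    )
    tol_outer = opts_outer.tol if opts_outer.tol is not None else 1e-6 * ep.kappa_star
    inner_tol = (
        opts_inner.tol if opts_inner.tol is not None else 1e-6 * ep.kappa_star
    )
    warm_k: dict[str, np.ndarray | None] = {"k": None}
    init_k_carry: np.ndarray | None = None

    def inner_solve(eps: np.ndarray) -> Solution:
        inner = solve_nash(
            params, grid, eps_path=eps, opts=opts_inner,
            init_k=warm_k["k"], auto_extend=False,
        )
        if not inner.converged and inner.residual > 10.0 * inner_tol:
            # the sweep can be defeated by oscillatory modes for some
            # intervention fields; fall back to Newton collocation
            logger.info(
                "inner sweep stalled at residual %.3e; switching to collocation",
                inner.residual,
            )
            inner = solve_nash_bvp(params, grid, eps, init_k=warm_k["k"], bvp_tol=1e-7)
            if not inner.converged and inner.residual > 10.0 * inner_tol:
                raise RuntimeError(
                    f"inner equilibrium unsolvable at this intervention field "
                    f"(sweep and collocation both stalled; residual "
                    f"{inner.residual:.3e})"
                )
        return inner

    def outer_step(eps: np.ndarray):
        inner = inner_solve(eps)
        warm_k["k"] = inner.traj.k
        gov = government_costates(inner.traj, inner.costates, gp, up)
        cand = epsilon_update(inner.traj, inner.costates, gov, gp, up)
        return cand, (inner, gov)

    method = "sweep"
    for attempt in range(max_extensions + 1):
        if init_eps is None:
            eps0, ansatz_k = decentralization_ansatz(params, grid)
            warm_k["k"] = ansatz_k if init_k_carry is None else init_k_carry
        else:
            eps0 = np.asarray(init_eps, float)
            warm_k["k"] = init_k_carry
        if eps0.shape != (grid.n,):
            raise ValueError(f"init_eps must have shape ({grid.n},)")

        res = anderson_fixed_point(
            outer_step, eps0, tol_outer, opts_outer, label="government", mixing=0.5
        )
        if res.aux is None:
            raise RuntimeError("government outer iteration made no progress")
        inner, gov = res.aux
        method = "sweep"
        if not res.converged:
            # Newton collocation on the full six-state optimality system,
            # warm-started from the best outer iterate
            logger.info(
                "outer iteration stalled at residual %.3e; "
                "trying government collocation", res.residual,
            )
            try:
                eps_b = _government_bvp_eps(params, grid, inner, gov)
                inner_b = inner_solve(eps_b)
                gov_b = government_costates(inner_b.traj, inner_b.costates, gp, up)
                cand_b = epsilon_update(inner_b.traj, inner_b.costates, gov_b, gp, up)
                resid_b = float(np.max(np.abs(cand_b - eps_b)))
                V_b = evaluate_objective(inner_b.traj, "government", up, gp)
                V_a = evaluate_objective(inner.traj, "government", up, gp)
                # Newton may jump to a *different* (possibly worse) local
                # optimum — e.g. from a nearly-stationary high-peak iterate
                # onto the tracking branch — so a stalled sweep iterate that
                # is itself nearly stationary (within 100x tol) is kept when
                # its objective is better; anything further from
                # stationarity is not a solution at all and is replaced by
                # the collocation optimum unconditionally.
                if V_b >= V_a - 1e-6 * abs(V_a) or res.residual > 100.0 * tol_outer:
                    inner, gov = inner_b, gov_b
                    res.residual = resid_b
                    method = "collocation"
            except (RuntimeError, ValueError) as err:
                logger.warning("government collocation fallback failed: %s", err)
        if not auto_extend or inner.traj.i[-1] <= BURNOUT_THRESHOLD or attempt == max_extensions:
            break
        new_grid = grid.extended()
        logger.info(
            "i(tf)=%.2e: extending government horizon %.4g -> %.4g",
            inner.traj.i[-1], grid.tf, new_grid.tf,
        )
        init_eps = np.interp(new_grid.nodes, grid.nodes, inner.traj.eps, right=0.0)
        init_k_carry = np.interp(
            new_grid.nodes, grid.nodes, inner.traj.k, right=ep.kappa_star
        )
        grid = new_grid

    V = evaluate_objective(inner.traj, "government", up, gp)
    out = GovernmentSolution(
        solution=inner,
        gov_costates=gov,
        inner_costates=inner.costates,
        V=V,
        branch_label=_branch_label(inner, gp),
        converged=(res.converged or method == "collocation") and inner.converged,
        iterations=res.iterations,
        residual=res.residual,
        method=method,
    )
    out.all_local_optima = [(inner.traj.eps.copy(), V)]
    return out


def _government_bvp_eps(
    params: ModelParams,
    grid: TimeGrid,
    inner: Solution,
    gov: GovernmentCostates,
    bvp_tol: float = 1e-8,
) -> np.ndarray:
    """Newton collocation on the six-state government optimality system.

    States (s, i, v_s, v_i, λ_s, λ_i); both controls are eliminated through
    their pointwise stationarity rules. Returns the optimal intervention
    field evaluated at the grid nodes; raises RuntimeError on failure.
    """
    from scipy.integrate import solve_bvp

    gp, up, ep = params.government, params.utility, params.epidemic
    lnf, lnfg = up.log_f, gp.log_f_g
    beta, kstar = up.beta, ep.kappa_star
    bg, gg = gp.beta_g, gp.gamma_g
    ucost, gcost = up.cost, gp.cost_g
    vi_T = -math.exp(-grid.tf * lnf) * ucost.alpha_at_zero() / (1.0 + lnf)
    li_T = -math.exp(-grid.tf * lnfg) * gcost.alpha_at_zero() / (1.0 + lnfg)

    def rhs(t, y):
        s, i, vs, vi, ls, li = y
        ft = np.exp(t * lnf)
        fgt = np.exp(t * lnfg)
        dfg = np.exp(-t * lnfg)
        disc = np.exp(-t * lnf)
        epsv = i * s * (ft * (bg + gg) * (vs - vi) - fgt * (ls - li)) / (bg + 2.0 * gg)
        k = np.maximum(
            kstar - 0.5 * ft * (vs - vi) * s * i / beta + 0.5 * epsv / beta, 0.0
        )
        lam = -(li - ls) * (kstar + 0.5 * epsv) + dfg * 0.5 * ft * (vi - vs) * (
            i * s * (bg * ft * (vi - vs) - 2.0 * fgt * (li - ls))
            + epsv * (gg + bg)
        )
        a = infection_cost(i, ucost)
        ag = infection_cost(i, gcost)
        agp = infection_cost_derivative(i, gcost)
        return np.vstack(
            [
                -k * s * i,
                k * s * i - i,
                (vs - vi) * k * i,
                disc * a + vi,
                i * lam,
                s * lam + dfg * (ag + agp * i) + li,
            ]
        )

    def bc(ya, yb):
        return np.array(
            [ya[0] - ep.s0, ya[1] - ep.i0, yb[2], yb[3] - vi_T, yb[4], yb[5] - li_T]
        )

    nodes = grid.nodes
    stride = max(1, (grid.n - 1) // 1000)
    mesh = nodes[::stride]
    if mesh[-1] != nodes[-1]:
        mesh = np.append(mesh, nodes[-1])
    y0 = np.vstack(
        [
            np.interp(mesh, nodes, inner.traj.s),
            np.interp(mesh, nodes, inner.traj.i),
            np.interp(mesh, nodes, inner.costates.v_s),
            np.interp(mesh, nodes, inner.costates.v_i),
            np.interp(mesh, nodes, gov.lambda_s),
            np.interp(mesh, nodes, gov.lambda_i),
        ]
    )
    with np.errstate(over="ignore", invalid="ignore"):
        # Newton trial iterates may transiently overflow; harmless
        bvp = solve_bvp(rhs, bc, mesh, y0, tol=bvp_tol, max_nodes=40_000)
    if not bvp.success:
        raise RuntimeError(f"government BVP: {bvp.message}")
    y = bvp.sol(nodes)
    ft = np.exp(nodes * lnf)
    fgt = np.exp(nodes * lnfg)
    return (
        y[1] * y[0]
        * (ft * (bg + gg) * (y[2] - y[3]) - fgt * (y[4] - y[5]))
        / (bg + 2.0 * gg)
    )


def _distinct(eps_a: np.ndarray, eps_b: np.ndarray, grids_match: bool) -> bool:
    if not grids_match or eps_a.shape != eps_b.shape:
        n = min(eps_a.shape[0], eps_b.shape[0])
        return bool(np.max(np.abs(eps_a[:n] - eps_b[:n])) > DISTINCT_OPTIMA_TOL)
    return bool(np.max(np.abs(eps_a - eps_b)) > DISTINCT_OPTIMA_TOL)


def _with_alpha_g1(params: ModelParams, alpha_g1: float) -> ModelParams:
    gp = params.government
    return replace(
        params, government=replace(gp, cost_g=replace(gp.cost_g, alpha1=alpha_g1))
    )


def branch_scan(
    params: ModelParams,
    alpha_g1_values,
    grid: TimeGrid | None = None,
    opts_inner: SweepOptions | None = None,
    opts_outer: SweepOptions | None = None,
) -> list[GovernmentSolution]:
    """Trace both local-optimum branches of the government problem over α_g1.

    For each maximum infection cost in the (ascending) list, the solver is
    started (a) from ε ≡ 0, (b) from the decentralization ansatz, and (c) by
    continuation from the neighbouring solutions in each direction, so that
    both the high-peak and the threshold-tracking branch are followed
    through the region where they coexist. Distinct converged optima
    (sup-norm ε distance > 1e-2) are recorded in each returned solution's
    ``all_local_optima`` (as (ε, V) pairs); the stored solution is the
    argmax of V. Exactly two distinct optima are expected near the switch;
    more is logged as an anomaly. Starts whose solve fails outright are
    dropped (logged).
    """
    if params.government is None:
        raise ValueError("params.government is required")
    if params.government.cost_g.constant:
        logger.info("constant government cost: single branch expected")
    values = list(alpha_g1_values)
    if sorted(values) != values:
        raise ValueError("alpha_g1_values must be ascending")
    grid = grid or TimeGrid()

    def solve_from(a1: float, init_eps, start_grid: TimeGrid):
        p = _with_alpha_g1(params, a1)
        try:
            return solve_government(
                p, grid=start_grid, opts_inner=opts_inner, opts_outer=opts_outer,
                init_eps=init_eps,
            )
        except RuntimeError as err:
            logger.warning("scan solve at alpha_g1=%.6g failed: %s", a1, err)
            return None

    # ascending pass: cold start, ansatz, and continuation from the left
    candidates: list[list[GovernmentSolution]] = []
    prev: GovernmentSolution | None = None
    for a1 in values:
        found = [
            g
            for g in (
                solve_from(a1, np.zeros(grid.n), grid),
                solve_from(a1, None, grid),
            )
            if g is not None
        ]
        if prev is not None:
            cont = solve_from(a1, prev.solution.traj.eps, prev.solution.grid)
            if cont is not None:
                found.append(cont)
        if not found:
            raise RuntimeError(f"no government solve succeeded at alpha_g1={a1}")
        candidates.append(found)
        prev = max(found, key=lambda g: g.V)
    # descending pass: continuation from the right
    nxt: GovernmentSolution | None = None
    for idx in range(len(values) - 1, -1, -1):
        if nxt is not None:
            cont = solve_from(
                values[idx], nxt.solution.traj.eps, nxt.solution.grid
            )
            if cont is not None:
                candidates[idx].append(cont)
        nxt = max(candidates[idx], key=lambda g: g.V)

    results: list[GovernmentSolution] = []
    kstar = params.epidemic.kappa_star
    for a1, found in zip(values, candidates):
        # keep converged optima and near-stationary sweep iterates (these
        # carry branches whose discrete outer map cannot be polished); drop
        # outright failures unless nothing else survived
        acceptable = [
            g for g in found if g.converged or g.residual < 0.01 * kstar
        ]
        found = acceptable or found
        distinct: list[GovernmentSolution] = []
        for g in found:
            if all(
                _distinct(
                    g.solution.traj.eps, h.solution.traj.eps,
                    g.solution.grid.same_as(h.solution.grid),
                )
                for h in distinct
            ):
                distinct.append(g)
        if len(distinct) > 2:
            logger.warning(
                "alpha_g1=%.6g: %d distinct local optima found (expected <= 2)",
                a1, len(distinct),
            )
        best = max(distinct, key=lambda g: g.V)
        best.all_local_optima = [
            (g.solution.traj.eps.copy(), g.V) for g in distinct
        ]
        results.append(best)
    return results


def find_switch(alpha_g1_values, solutions: list[GovernmentSolution]) -> float | None:
    """First α_g1 at which the selected branch label changes, or None."""
    for a1_prev, a1, prev, cur in zip(
        alpha_g1_values, list(alpha_g1_values)[1:], solutions, solutions[1:]
    ):
        if cur.branch_label != prev.branch_label:
            return float(a1)
    return None
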