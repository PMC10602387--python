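"""Independent verification: direct transcription, stationarity, fixed points.

The sweep solvers are checked against machinery that shares none of their
costate code: (i) a direct-transcription optimizer that parameterises the
control on a coarse node set and maximises the simulate-then-quadrature
objective with a general-purpose bounded optimizer; (ii) finite-difference
stationarity residuals of the relevant Hamiltonian along converged paths;
(iii) a best-response check of the Nash fixed-point property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .costs import evaluate_objective, infection_cost
from .epidemic import integrate_sir
from .grid import TimeGrid
from .nash import best_response, individual_objective, solve_nash
from .params import ModelParams
from .sweep import SweepOptions
from . import _kernels
from .trajectory import GovernmentSolution, Solution

__all__ = [
    "TranscriptionSpec",
    "direct_transcription_optimize",
    "pontryagin_residual",
    "verify_nash_fixed_point",
    "FixedPointReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptionSpec:
    """Coarse control parameterisation for the transcription oracle.

    The control is piecewise linear on ``n_nodes`` uniform nodes; coarse
    controls cannot match fine-grid sweep paths pointwise, so agreement is
    asserted on objective values.
    """

    objective_kind: str = "population"  # individual | population | government
    n_nodes: int = 40
    n_restarts: int = 3
    maxiter: int = 500

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError(f"n_nodes must be >= 4, got {self.n_nodes}")
        if self.objective_kind not in {"individual", "population", "government"}:
            raise ValueError(f"unknown objective_kind {self.objective_kind!r}")


@dataclass
class TranscriptionResult:
    control: np.ndarray  # on the fine grid
    objective: float
    success: bool


def direct_transcription_optimize(
    spec: TranscriptionSpec,
    params: ModelParams,
    grid: TimeGrid | None = None,
    fixed_k: np.ndarray | None = None,
    fixed_eps: np.ndarray | None = None,
    seed: int = 0,
    inner_opts: SweepOptions | None = None,
) -> TranscriptionResult:
    """Maximise an objective over a coarse piecewise-linear control.

    individual:  optimises the individual's κ against the frozen population
                 behaviour ``fixed_k`` (required) and ``fixed_eps``.
    population:  optimises the population behaviour k (``fixed_eps`` is the
                 exogenous intervention, default 0).
    government:  optimises ε; every evaluation re-solves the inner Nash
                 equilibrium (warm-started across evaluations).

    Uses L-BFGS-B with bounds (k, κ ≥ 0; ε unbounded) and seeded multi-start;
    no costate equation is touched, keeping the oracle independent of the
    sweep implementation.
    """
    grid = grid or TimeGrid()
    ep, up, gp = params.epidemic, params.utility, params.government
    tcoarse = np.linspace(grid.t0, grid.tf, spec.n_nodes)
    tfine = grid.nodes
    eps_fixed = np.zeros(grid.n) if fixed_eps is None else np.asarray(fixed_eps, float)
    rng = np.random.default_rng(seed)

    if spec.objective_kind == "individual":
        if fixed_k is None:
            raise ValueError("individual objective requires fixed_k")
        pop = integrate_sir(np.asarray(fixed_k, float), ep, grid, eps_path=eps_fixed)

        def objective(x: np.ndarray) -> float:
            kappa = np.interp(tfine, tcoarse, x)
            ps, pi = _kernels.psi_forward(kappa, pop.i, ep.s0, ep.i0, grid.dt)
            return individual_objective(kappa, ps, pi, pop, up)

        x_base = np.full(spec.n_nodes, ep.kappa_star)
        bounds = [(0.0, None)] * spec.n_nodes
        scale = 0.5 * ep.kappa_star
    elif spec.objective_kind == "population":

        def objective(x: np.ndarray) -> float:
            k = np.interp(tfine, tcoarse, x)
            traj = integrate_sir(k, ep, grid, eps_path=eps_fixed)
            return evaluate_objective(traj, "population", up, gp)

        x_base = np.full(spec.n_nodes, ep.kappa_star)
        bounds = [(0.0, None)] * spec.n_nodes
        scale = 0.5 * ep.kappa_star
    else:  # government
        if gp is None:
            raise ValueError("government objective requires params.government")
        warm: dict[str, np.ndarray | None] = {"k": None}
        inner_opts = inner_opts or SweepOptions()

        def objective(x: np.ndarray) -> float:
            eps = np.interp(tfine, tcoarse, x)
            inner = solve_nash(
                params, grid, eps_path=eps, opts=inner_opts,
                init_k=warm["k"], auto_extend=False,
            )
            warm["k"] = inner.traj.k
            return evaluate_objective(inner.traj, "government", up, gp)

        x_base = np.zeros(spec.n_nodes)
        bounds = None
        scale = 1.0

    starts = [x_base]
    for _ in range(max(spec.n_restarts - 1, 0)):
        perturbed = x_base + scale * rng.standard_normal(spec.n_nodes)
        if bounds is not None:
            perturbed = np.maximum(perturbed, 0.0)
        starts.append(perturbed)

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            lambda x: -objective(x),
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": spec.maxiter, "maxfun": 10 * spec.maxiter * spec.n_nodes},
        )
        any_success = any_success or bool(res.success)
        if best is None or -res.fun > -best.fun:
            best = res
    if not any_success:
        logger.warning("transcription optimizer reported failure on every start")
    control_fine = np.interp(tfine, tcoarse, best.x)
    return TranscriptionResult(
        control=control_fine, objective=float(-best.fun), success=any_success
    )


def _hamiltonian_kappa_derivative(sol: Solution, params: ModelParams, population: bool):
    """Central-difference dH/dκ per node, in utility-rate units."""
    traj, cs = sol.traj, sol.costates
    up = params.utility
    t = traj.grid.nodes
    disc = np.exp(-t * up.log_f)
    delta = 1e-3 * params.epidemic.kappa_star

    def H(kappa: np.ndarray) -> np.ndarray:
        dk = kappa - traj.kappa_star
        return (
            -disc
            * (
                infection_cost(traj.i, up.cost) * traj.i
                + up.beta * dk**2
                - traj.eps * dk
            )
            - (cs.v_s - cs.v_i) * kappa * traj.s * traj.i
            - cs.v_i * traj.i
        )

    return (H(traj.k + delta) - H(traj.k - delta)) / (2.0 * delta)


def _hamiltonian_eps_derivative(gsol: GovernmentSolution, params: ModelParams):
    """Central-difference dH_g/dε per node, with k(ε) from the inner rule."""
    up, gp, ep = params.utility, params.government, params.epidemic
    traj = gsol.solution.traj
    v = gsol.inner_costates
    lam = gsol.gov_costates
    t = traj.grid.nodes
    ft = np.exp(t * up.log_f)
    dfg = np.exp(-t * gp.log_f_g)
    delta = 1e-3 * ep.kappa_star

    def H(eps: np.ndarray) -> np.ndarray:
        k = np.maximum(
            ep.kappa_star
            - 0.5 * ft * (v.v_s - v.v_i) * traj.s * traj.i / up.beta
            + 0.5 * eps / up.beta,
            0.0,
        )
        dk = k - traj.kappa_star
        return (
            -dfg
            * (
                infection_cost(traj.i, gp.cost_g) * traj.i
                + gp.beta_g * dk**2
                + gp.gamma_g * eps * dk
            )
            - (lam.lambda_s - lam.lambda_i) * k * traj.s * traj.i
            - lam.lambda_i * traj.i
        )

    return (H(traj.eps + delta) - H(traj.eps - delta)) / (2.0 * delta)


def pontryagin_residual(
    sol: Solution | GovernmentSolution,
    params: ModelParams,
    kind: str,
    active_tol: float = 1e-12,
) -> float:
    """Max scaled stationarity violation of the relevant Hamiltonian.

    kind: 'nash' | 'utilitarian' | 'government'. The finite-difference
    control derivative of the Hamiltonian is evaluated along the converged
    path and scaled into control units (divided by the Hamiltonian's own
    curvature), so the residual is comparable to the sweep tolerance. Nodes
    where the control bound is active contribute only if the one-sided
    optimality condition (dH/dκ ≤ 0 at κ = 0) is violated.
    """
    if kind == "government":
        if not isinstance(sol, GovernmentSolution):
            raise TypeError("government residual needs a GovernmentSolution")
        gp, up = params.government, params.utility
        dH = _hamiltonian_eps_derivative(sol, params)
        t = sol.solution.grid.nodes
        curvature = np.exp(-t * gp.log_f_g) * (gp.beta_g + 2.0 * gp.gamma_g) / 2.0
        scaled = dH / curvature
        # ε is unbounded, but nodes where the *inner* bound k = 0 binds sit on
        # the kink of k(ε) and are excluded from the interior test.
        interior = sol.solution.traj.k > active_tol
        return float(np.max(np.abs(scaled[interior]))) if interior.any() else 0.0
    if kind not in {"nash", "utilitarian"}:
        raise ValueError(f"unknown kind {kind!r}")
    up = params.utility
    dH = _hamiltonian_kappa_derivative(sol, params, population=(kind == "utilitarian"))
    t = sol.grid.nodes
    curvature = 2.0 * up.beta * np.exp(-t * up.log_f)
    scaled = dH / curvature
    k = sol.traj.k
    interior = k > active_tol
    resid = np.abs(scaled) * interior
    # at the bound, dH/dκ must not be positive (no gain from raising κ)
    resid = np.where(~interior & (scaled > 0), scaled, resid)
    return float(np.max(resid))


@dataclass(frozen=True)
class FixedPointReport:
    """Best-response audit of a candidate equilibrium."""

    gap: float  # sup |best response − population behaviour|
    utility_gain: float  # U(best response) − U(population strategy)


def verify_nash_fixed_point(
    sol: Solution,
    params: ModelParams,
    opts: SweepOptions | None = None,
) -> FixedPointReport:
    """Audit the Nash property: no individual gains by deviating.

    Recomputes the best response to the solution's population behaviour with
    an independent sweep over the individual's own compartment probabilities
    and reports the sup-norm control gap and the utility a defector gains.
    A converged Nash solution yields a gap below the sweep tolerance and an
    (essentially zero) non-negative gain; feeding in a utilitarian solution
    exposes a macroscopic profitable defection.
    """
    grid = sol.grid
    kappa, u_br = best_response(
        sol.traj.k, params, grid=grid, eps_path=sol.traj.eps, opts=opts
    )
    ep, up = params.epidemic, params.utility
    pop = sol.traj
    ps, pi = _kernels.psi_forward(pop.k, pop.i, ep.s0, ep.i0, grid.dt)
    u_pop = individual_objective(pop.k, ps, pi, pop, up)
    return FixedPointReport(
        gap=float(np.max(np.abs(kappa - sol.traj.k))),
        utility_gain=float(u_br - u_pop),
    )
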