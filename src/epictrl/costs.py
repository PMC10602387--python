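"""Infection cost with healthcare threshold, salvage terms, and objectives.

The per-infection cost α(i) is either constant or rises from α0 to α1 in a
tanh step around the healthcare threshold i_hc, modelling the deterioration
of care (and rising fatality) once the infected fraction saturates hospital
capacity. All utilities are discounted with weight f^(−t); the tail of the
epidemic beyond the horizon tf contributes the closed-form salvage term

    U_f ≈ −f^(−tf) α(0) i_f / (1 + ln f),

which is exact in the limit where, after tf, infections decay as e^(−(t−tf))
with α ≈ α(0) (epidemic essentially burnt out).
"""

from __future__ import annotations

import math

import numpy as np

from .params import GovernmentParams, InfectionCostParams, UtilityParams
from .trajectory import Trajectory

__all__ = [
    "infection_cost",
    "infection_cost_derivative",
    "salvage_individual",
    "evaluate_objective",
]


def infection_cost(i, p: InfectionCostParams):
    """α(i); accepts a scalar or array of infected fractions."""
    i = np.asarray(i, dtype=float)
    if p.constant:
        out = np.full_like(i, p.alpha0)
    else:
        out = p.alpha0 + 0.5 * (p.alpha1 - p.alpha0) * (
            np.tanh((i - p.i_hc) * p.sigma) + 1.0
        )
    return out if out.ndim else float(out)


def infection_cost_derivative(i, p: InfectionCostParams):
    """dα/di = (α1 − α0)·σ/2 · sech²[(i − i_hc)σ]; zero for constant cost."""
    i = np.asarray(i, dtype=float)
    if p.constant:
        out = np.zeros_like(i)
    else:
        # sech²(x) via exp(-|x|) to avoid cosh overflow for large arguments
        x = np.abs((i - p.i_hc) * p.sigma)
        e = np.exp(-x)
        sech = 2.0 * e / (1.0 + e * e)
        out = 0.5 * (p.alpha1 - p.alpha0) * p.sigma * sech**2
    return out if out.ndim else float(out)


def salvage_individual(
    i_f: float, f: float, tf: float, p: InfectionCostParams
) -> float:
    """Closed-form tail utility −f^(−tf)·α(0)·i_f/(1 + ln f).

    The same expression serves the government objective with (f_g, α_g)
    substituted. At f = 1 the divisor is 1 (natural-log convention).
    """
    return -(f ** (-tf)) * p.alpha_at_zero() * i_f / (1.0 + math.log(f))


_WHICH = {"individual", "individual-at-equilibrium", "population", "government"}


def evaluate_objective(
    traj: Trajectory,
    which: str,
    up: UtilityParams,
    gp: GovernmentParams | None = None,
) -> float:
    """Trapezoidal value of one of the three objective functionals.

    which:
        'individual' (alias 'individual-at-equilibrium') — the representative
        individual's utility evaluated at equilibrium, where the individual's
        compartment probabilities coincide with the population fractions
        (ψ_s = s, ψ_i = i):   ∫ f^(−t)[−α(i)·i − β(k−κ*)² + (k−κ*)ε] dt + U_f
        'population' — the utilitarian objective U_p (same integrand).
        'government' — ∫ f_g^(−t)[−α_g(i)·i − β_g(k−κ*)² − γ_g·ε(k−κ*)] dt + V_f.

    Returns utility (higher is better); cost is its negative.
    """
    if which not in _WHICH:
        raise ValueError(f"unknown objective {which!r}; expected one of {_WHICH}")
    if traj.kappa_star is None:
        raise ValueError("trajectory lacks kappa_star; integrate via integrate_sir")
    t = traj.grid.nodes
    i = traj.i
    dk = traj.k - traj.kappa_star
    if which == "government":
        if gp is None:
            raise ValueError("government objective requires GovernmentParams")
        disc = np.exp(-t * gp.log_f_g)
        integrand = disc * (
            -infection_cost(i, gp.cost_g) * i
            - gp.beta_g * dk**2
            - gp.gamma_g * traj.eps * dk
        )
        tail = salvage_individual(float(i[-1]), gp.f_g, traj.grid.tf, gp.cost_g)
    else:
        disc = np.exp(-t * up.log_f)
        integrand = disc * (
            -infection_cost(i, up.cost) * i - up.beta * dk**2 + traj.eps * dk
        )
        tail = salvage_individual(float(i[-1]), up.f, traj.grid.tf, up.cost)
    return float(np.trapezoid(integrand, dx=traj.grid.dt) + tail)
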