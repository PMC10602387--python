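"""SIR integration under a prescribed behaviour path, and summary metrics.

The rescaled SIR model (unit recovery rate) is

    s' = -k(t) s i,    i' = k(t) s i - i,

with s(0) = 1 - i0, i(0) = i0. Behaviour k(t) aggregates the population's
social distancing: k = κ* means business as usual, k < κ* distancing.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .grid import TimeGrid
from .params import EpidemicParams
from .trajectory import EpidemicSummary, Trajectory

__all__ = [
    "integrate_sir",
    "summarize",
    "final_size_root",
    "DURATION_THRESHOLD",
    "BURNOUT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Infected fraction above which the epidemic counts as "ongoing" for the
#: duration metric.
DURATION_THRESHOLD = 1e-4

#: i(tf) must fall below this for the horizon to count as long enough (the
#: closed-form salvage term assumes a nearly burnt-out epidemic).
BURNOUT_THRESHOLD = 1e-8

# Negative undershoot beyond this is an integration failure; smaller
# undershoot is clamped to zero.
_CLAMP_TOL = 1e-12


def _clamp_nonnegative(arr: np.ndarray, name: str) -> np.ndarray:
    worst = arr.min()
    if not np.isfinite(worst):
        # distinguishes a solver-iterate overflow (recoverable upstream)
        # from invalid user input
        raise RuntimeError(f"SIR integration overflowed ({name} is non-finite)")
    if worst < -_CLAMP_TOL:
        raise RuntimeError(
            f"{name} undershoots zero by {-worst:.3e} (> {_CLAMP_TOL}); "
            "refine the grid"
        )
    if worst < 0.0:
        logger.warning("clamping tiny negative values of %s (min %.3e)", name, worst)
        arr = np.maximum(arr, 0.0)
    return arr


def integrate_sir(
    k_path: np.ndarray,
    params: EpidemicParams,
    grid: TimeGrid,
    eps_path: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the SIR model with a time-varying behaviour path.

    Fixed-step RK4 on the uniform grid (controls interpolated linearly at
    half-steps), so identical inputs give bit-identical outputs.

    Parameters
    ----------
    k_path:
        Behaviour (infectiousness) at the grid nodes; must be finite and >= 0.
    eps_path:
        Optional intervention path carried along in the returned trajectory
        (it does not influence the dynamics directly — only through k).
    """
    k = np.asarray(k_path, dtype=float)
    if k.shape != (grid.n,):
        raise ValueError(f"k_path must have shape ({grid.n},), got {k.shape}")
    if np.any(~np.isfinite(k)):
        raise ValueError("k_path contains NaN or Inf")
    if np.any(k < 0):
        raise ValueError("k_path must be non-negative")
    s, i = _kernels.sir_forward(k, params.s0, params.i0, grid.dt)
    s = _clamp_nonnegative(s, "s")
    i = _clamp_nonnegative(i, "i")
    if eps_path is None:
        eps = np.zeros(grid.n)
    else:
        eps = np.asarray(eps_path, dtype=float)
        if eps.shape != (grid.n,):
            raise ValueError(f"eps_path must have shape ({grid.n},)")
    return Trajectory(
        grid=grid, s=s, i=i, k=k, eps=eps, kappa_star=params.kappa_star
    )


def summarize(
    traj: Trajectory,
    total_cost: float = float("nan"),
    duration_threshold: float = DURATION_THRESHOLD,
) -> EpidemicSummary:
    """Headline metrics: peak infections, total cases 1 - s(tf), duration.

    Duration is the measure of {t : i(t) > threshold}, computed as the node
    count above threshold times dt.
    """
    above = traj.i > duration_threshold
    return EpidemicSummary(
        peak_i=float(traj.i.max()),
        total_cases=float(1.0 - traj.s[-1]),
        s_inf=float(traj.s[-1]),
        duration=float(above.sum() * traj.grid.dt),
        total_cost=float(total_cost),
    )


def final_size_root(
    R0: float, s0: float = 1.0, i0: float = 0.0, tol: float = 1e-12
) -> float:
    """Final susceptible fraction from the SIR final-size relation.

    Solves s_inf = s0 * exp(-R0 * (s0 + i0 - s_inf)) for s_inf in (0, s0] by
    bracketed root-finding; used as the analytic oracle for constant-k runs.
    """
    if not R0 > 0:
        raise ValueError(f"R0 must be > 0, got {R0}")

    def g(x: float) -> float:
        return x - s0 * np.exp(-R0 * (s0 + i0 - x))

    lo = s0 * 1e-16
    hi = s0
    glo, ghi = g(lo), g(hi)
    if ghi == 0.0:
        return hi
    if glo * ghi > 0:
        raise RuntimeError(
            f"no sign change on bracket ({lo:.3e}, {hi:.3e}) for R0={R0}"
        )
    return float(brentq(g, lo, hi, xtol=tol, rtol=8.9e-16))
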