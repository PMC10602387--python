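"""Damped fixed-point driver shared by all forward-backward sweeps."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "SweepOptions",
    "damped_fixed_point",
    "anderson_fixed_point",
    "SweepResult",
]

logger = logging.getLogger(__name__)


@dataclass
class SweepOptions:
    """Tuning knobs of the forward-backward sweep.

    relaxation:
        Mixing weight ω of the control update, x ← (1−ω)x + ω·candidate.
        Small values trade speed for stability; the candidate map is not a
        contraction near the epidemic peak without damping.
    tol:
        Convergence threshold on the *unrelaxed* residual sup|candidate − x|.
        ``None`` defers to the solver default (1e-6 · κ* in control units).
        The unrelaxed residual is the distance to the fixed point that the
        optimality conditions see, so stationarity residuals inherit it
        directly, unlike the post-mixing step size which understates it by ω.
    max_iter:
        Iteration cap; exceeding it returns a flagged (non-converged) result.
    patience:
        Number of iterations without a new best residual before the
        relaxation is halved (the oscillation cure); a healthy converging
        sweep improves its best residual far more often than this.
    """

    relaxation: float = 0.1
    tol: float | None = None
    max_iter: int = 10000
    verbose: bool = False
    min_relaxation: float | None = None  # default: relaxation / 1024
    patience: int = 50
    #: history window of the Anderson-accelerated outer iteration (the nested
    #: government solve); 0 falls back to plain damped mixing
    anderson_window: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError(f"relaxation must be in (0, 1], got {self.relaxation}")
        if self.tol is not None and not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.min_relaxation is None:
            self.min_relaxation = self.relaxation / 1024.0


@dataclass
class SweepResult:
    x: np.ndarray
    aux: object
    converged: bool
    iterations: int
    residual: float


def damped_fixed_point(
    step: Callable[[np.ndarray], tuple[np.ndarray, object]],
    x0: np.ndarray,
    tol: float,
    opts: SweepOptions,
    label: str = "sweep",
) -> SweepResult:
    """Iterate x ← (1−ω)x + ω·step(x) until sup|step(x) − x| < tol.

    ``step`` returns (candidate, aux) where aux carries whatever state the
    caller wants for the point x (trajectory, costates). On sustained residual
    growth the relaxation ω is halved (down to ``min_relaxation``) — the
    standard cure for the overshoot oscillations of an undamped sweep.
    """
    x = np.array(x0, dtype=float)
    omega = opts.relaxation
    best_resid = np.inf
    bad = 0
    aux = None
    prev_x = x.copy()
    for it in range(1, opts.max_iter + 1):
        cand, aux = step(x)
        resid = float(np.max(np.abs(cand - x)))
        if not np.isfinite(resid):
            logger.warning("%s iter %d: non-finite candidate, aborting", label, it)
            return SweepResult(
                x=prev_x, aux=aux, converged=False, iterations=it, residual=np.inf
            )
        prev_x = x.copy()
        if opts.verbose and (it % 50 == 0 or resid < tol):
            logger.info("%s iter %d: residual %.3e (omega %.3g)", label, it, resid, omega)
        if resid < tol:
            return SweepResult(x=x, aux=aux, converged=True, iterations=it, residual=resid)
        # Oscillation/divergence cure: a healthy damped sweep improves its
        # best residual every few iterations (transients included); when no
        # new best appears for `patience` iterations the map is cycling or
        # diverging at this relaxation, so halve it and try again.
        if resid < best_resid:
            best_resid = resid
            bad = 0
        else:
            bad += 1
            if bad >= opts.patience:
                omega = max(omega / 2.0, opts.min_relaxation)
                logger.info(
                    "%s iter %d: no residual improvement in %d iterations "
                    "(%.3e vs best %.3e), halving relaxation to %.3g",
                    label, it, opts.patience, resid, best_resid, omega,
                )
                bad = 0
        x = (1.0 - omega) * x + omega * cand
    logger.warning(
        "%s failed to converge in %d iterations (residual %.3e)",
        label, opts.max_iter, resid,
    )
    return SweepResult(x=x, aux=aux, converged=False, iterations=opts.max_iter, residual=resid)


def anderson_fixed_point(
    step: Callable[[np.ndarray], tuple[np.ndarray, object]],
    x0: np.ndarray,
    tol: float,
    opts: SweepOptions,
    label: str = "anderson",
    mixing: float = 0.5,
    lower_bound: float | None = None,
) -> SweepResult:
    """Anderson-accelerated fixed-point iteration with damped safeguards.

    Extrapolates over a short history of (iterate, residual) pairs — the
    type-II Anderson scheme, equivalent to a secant approximation of the
    Newton step — which converges fixed points whose plain damped iteration
    is oscillatory or slowly contracting. Safeguards: the history is flushed
    and the damping halved whenever the residual stagnates (``opts.patience``
    iterations without a new best), turns non-finite, or ``step`` raises
    ``RuntimeError`` (at most five times); in those cases the iteration
    restarts from the best iterate seen. Returns the best iterate, so a
    failed acceleration never degrades the starting point.
    """
    x = np.array(x0, dtype=float)
    omega = opts.relaxation
    beta = mixing
    hist_x: list[np.ndarray] = []
    hist_f: list[np.ndarray] = []
    best_resid = np.inf
    best_x = x.copy()
    best_aux = None
    bad = 0
    failures = 0
    it = 0
    while it < opts.max_iter:
        it += 1
        try:
            cand, aux = step(x)
        except RuntimeError as err:
            failures += 1
            logger.warning("%s iter %d: %s — restarting from best", label, it, err)
            if failures > 5:
                break
            x = best_x.copy()
            hist_x.clear()
            hist_f.clear()
            omega = max(omega / 2.0, opts.min_relaxation)
            beta /= 2.0
            continue
        f = cand - x
        resid = float(np.max(np.abs(f)))
        if not np.isfinite(resid):
            failures += 1
            logger.warning("%s iter %d: non-finite residual — restarting", label, it)
            if failures > 5:
                break
            x = best_x.copy()
            hist_x.clear()
            hist_f.clear()
            beta /= 2.0
            continue
        if opts.verbose and it % 10 == 0:
            logger.info("%s iter %d: residual %.3e", label, it, resid)
        if resid < best_resid:
            best_resid = resid
            best_x = x.copy()
            best_aux = aux
            bad = 0
        else:
            bad += 1
        if resid < tol:
            return SweepResult(x=x, aux=aux, converged=True, iterations=it, residual=resid)
        if bad >= opts.patience:
            logger.info(
                "%s iter %d: stagnating (%.3e vs best %.3e), flushing history",
                label, it, resid, best_resid,
            )
            x = best_x.copy()
            hist_x.clear()
            hist_f.clear()
            omega = max(omega / 2.0, opts.min_relaxation)
            bad = 0
            continue
        hist_x.append(x.copy())
        hist_f.append(f.copy())
        window = max(int(opts.anderson_window), 1)
        if len(hist_x) > window:
            hist_x.pop(0)
            hist_f.pop(0)
        if len(hist_x) >= 2:
            dF = np.stack(
                [hist_f[j + 1] - hist_f[j] for j in range(len(hist_f) - 1)], axis=1
            )
            dX = np.stack(
                [hist_x[j + 1] - hist_x[j] for j in range(len(hist_x) - 1)], axis=1
            )
            try:
                gamma, *_ = np.linalg.lstsq(dF, f, rcond=1e-10)
                x = x + beta * f - (dX + beta * dF) @ gamma
            except np.linalg.LinAlgError:
                x = x + omega * f
        else:
            x = x + omega * f
        if lower_bound is not None:
            x = np.maximum(x, lower_bound)
    logger.warning(
        "%s did not converge in %d iterations (best residual %.3e)",
        label, it, best_resid,
    )
    return SweepResult(
        x=best_x, aux=best_aux, converged=False, iterations=it, residual=best_resid
    )
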