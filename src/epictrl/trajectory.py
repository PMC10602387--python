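"""Trajectory, costate, solution, and summary containers plus CSV/JSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import TimeGrid

__all__ = [
    "Trajectory",
    "CostateTrajectory",
    "GovernmentCostates",
    "EpidemicSummary",
    "Solution",
    "GovernmentSolution",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_summary_json",
    "read_summary_json",
]

# s or i dipping below -_CLAMP_TOL is an integration failure, not round-off.
_CLAMP_TOL = 1e-12


def _as_path(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


@dataclass
class Trajectory:
    """State and control paths on a shared grid.

    ``s``/``i`` are the susceptible/infected fractions, ``k`` the population
    behaviour (infectiousness), ``eps`` the government intervention field.
    The recovered fraction is implicit (r = 1 − s − i).
    """

    grid: TimeGrid
    s: np.ndarray
    i: np.ndarray
    k: np.ndarray
    eps: np.ndarray
    #: baseline behaviour κ* the controls are measured against (set by the
    #: integrator; objectives need it to price deviations from baseline)
    kappa_star: float | None = None

    def __post_init__(self) -> None:
        n = self.grid.n
        self.s = _as_path(self.s, n, "s")
        self.i = _as_path(self.i, n, "i")
        self.k = _as_path(self.k, n, "k")
        self.eps = _as_path(self.eps, n, "eps")

    def validate(self, tol: float = 1e-9) -> None:
        """Check physical invariants (within integration tolerance)."""
        if np.any(self.k < -tol):
            raise ValueError("behaviour path k has negative entries")
        for name, arr in (("s", self.s), ("i", self.i)):
            if np.any(arr < -_CLAMP_TOL * 10):
                raise ValueError(f"{name} undershoots 0 beyond tolerance")
        if np.any(self.s + self.i > 1.0 + tol):
            raise ValueError("s + i exceeds 1 beyond tolerance")
        if np.any(np.diff(self.s) > tol):
            raise ValueError("s is not non-increasing")


@dataclass
class CostateTrajectory:
    """Marginal-value (costate) paths v_s, v_i on the trajectory grid."""

    grid: TimeGrid
    v_s: np.ndarray
    v_i: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n
        self.v_s = _as_path(self.v_s, n, "v_s")
        self.v_i = _as_path(self.v_i, n, "v_i")


@dataclass
class GovernmentCostates:
    """Government costates λ_s, λ_i and the auxiliary integrand Λ."""

    grid: TimeGrid
    lambda_s: np.ndarray
    lambda_i: np.ndarray
    Lambda: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n
        self.lambda_s = _as_path(self.lambda_s, n, "lambda_s")
        self.lambda_i = _as_path(self.lambda_i, n, "lambda_i")
        self.Lambda = _as_path(self.Lambda, n, "Lambda")


@dataclass(frozen=True)
class EpidemicSummary:
    """Headline epidemic metrics.

    ``duration`` measures the time interval on which i exceeds the reporting
    threshold (default 1e-4); ``total_cost`` is the negative of whichever
    objective the producing solver optimised.
    """

    peak_i: float
    total_cases: float
    s_inf: float
    duration: float
    total_cost: float

    def to_dict(self) -> dict:
        return {
            "peak_i": self.peak_i,
            "total_cases": self.total_cases,
            "s_inf": self.s_inf,
            "duration": self.duration,
            "total_cost": self.total_cost,
        }


@dataclass
class Solution:
    """Output of an equilibrium or optimal-control solve.

    ``residual`` is the sup-norm distance between the control and its
    pointwise-optimality candidate on the shared fixed grid; ``converged``
    means that distance fell below the solver tolerance. ``method`` records
    which engine produced the result: "sweep" (damped forward-backward
    fixed point) or "collocation" (Newton boundary-value solve, used for
    stiff healthcare-threshold problems whose discrete sweep map is
    irreducibly unstable; there the residual reports the fixed-step
    discretization mismatch rather than a failure to solve).
    """

    traj: Trajectory
    costates: CostateTrajectory
    objective: float
    converged: bool
    iterations: int
    residual: float
    method: str = "sweep"

    @property
    def grid(self) -> TimeGrid:
        return self.traj.grid


@dataclass
class GovernmentSolution:
    """Output of the nested (Stackelberg) government optimisation.

    ``solution`` holds the induced Nash equilibrium under the optimal ε;
    ``all_local_optima`` records every distinct (ε path, V) the multi-start
    procedure found, of which the stored solution attains the maximum V.
    """

    solution: Solution
    gov_costates: GovernmentCostates
    inner_costates: CostateTrajectory
    V: float
    branch_label: str
    converged: bool
    iterations: int
    residual: float
    all_local_optima: list = field(default_factory=list)
    #: "sweep" (nested Anderson-accelerated sweep) or "collocation" (Newton
    #: solve of the six-state optimality system; used when the discrete
    #: outer map is too stiff to iterate, e.g. threshold-tracking policies)
    method: str = "sweep"


# ---------------------------------------------------------------------------
# I/O: plain-text CSV for paths, JSON for summaries.

def write_trajectory_csv(
    path: str | Path,
    traj: Trajectory,
    costates: CostateTrajectory | None = None,
    gov_costates: GovernmentCostates | None = None,
) -> None:
    cols: dict[str, np.ndarray] = {
        "t": traj.grid.nodes,
        "s": traj.s,
        "i": traj.i,
        "k": traj.k,
        "eps": traj.eps,
    }
    if costates is not None:
        cols["v_s"] = costates.v_s
        cols["v_i"] = costates.v_i
    if gov_costates is not None:
        cols["lambda_s"] = gov_costates.lambda_s
        cols["lambda_i"] = gov_costates.lambda_i
    # %.17g is lossless for float64 round-tripping
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path: str | Path):
    """Read a trajectory CSV; returns (Trajectory, CostateTrajectory | None)."""
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t"].to_numpy()
    n = len(t)
    grid = TimeGrid(tf=float(t[-1]), n=n, t0=float(t[0]))
    traj = Trajectory(
        grid=grid,
        s=df["s"].to_numpy(),
        i=df["i"].to_numpy(),
        k=df["k"].to_numpy(),
        eps=df["eps"].to_numpy() if "eps" in df else np.zeros(n),
    )
    costates = None
    if "v_s" in df and "v_i" in df:
        costates = CostateTrajectory(
            grid=grid, v_s=df["v_s"].to_numpy(), v_i=df["v_i"].to_numpy()
        )
    return traj, costates


def write_summary_json(path: str | Path, summary: EpidemicSummary, **extra) -> None:
    payload = summary.to_dict()
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_summary_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
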