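"""Scenario execution: dispatch, on-disk outputs, and figure-style tables."""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .epidemic import integrate_sir, summarize
from .government import branch_scan, find_switch, solve_government
from .nash import solve_nash
from .trajectory import write_summary_json, write_trajectory_csv
from .utilitarian import solve_utilitarian

__all__ = ["run_scenario", "make_figure_tables"]

logger = logging.getLogger(__name__)


def _provenance(cfg: ScenarioConfig) -> dict:
    # full resolved config (defaults included) so a run can be reproduced
    # from its output directory alone
    return json.loads(cfg.model_dump_json())


def _write_convergence(outdir: Path, **info) -> None:
    (outdir / "convergence.json").write_text(json.dumps(info, indent=2) + "\n")


def run_scenario(cfg: ScenarioConfig, outdir: str | Path) -> dict:
    """Run one scenario and write trajectory CSV + summary JSON to ``outdir``.

    Deterministic: identical configs byte-reproduce all outputs. Returns the
    summary dict that was written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg.model_params()
    grid = cfg.grid.build()
    opts = cfg.sweep.build()
    opts_outer = cfg.sweep_outer.build()
    (outdir / "config.json").write_text(
        json.dumps(_provenance(cfg), indent=2) + "\n"
    )

    if cfg.mode == "baseline":
        k = np.full(grid.n, params.epidemic.kappa_star)
        traj = integrate_sir(k, params.epidemic, grid)
        summary = summarize(traj, duration_threshold=cfg.duration_threshold)
        write_trajectory_csv(outdir / "trajectory.csv", traj)
        write_summary_json(outdir / "summary.json", summary, mode=cfg.mode)
        _write_convergence(outdir, mode=cfg.mode, converged=True, iterations=0)
        return summary.to_dict()

    if cfg.mode in ("nash", "utilitarian"):
        solver = solve_nash if cfg.mode == "nash" else solve_utilitarian
        sol = solver(params, grid, opts=opts)
        summary = summarize(
            sol.traj, -sol.objective, duration_threshold=cfg.duration_threshold
        )
        write_trajectory_csv(outdir / "trajectory.csv", sol.traj, sol.costates)
        write_summary_json(
            outdir / "summary.json", summary, mode=cfg.mode, objective=sol.objective
        )
        _write_convergence(
            outdir, mode=cfg.mode, converged=sol.converged,
            iterations=sol.iterations, residual=sol.residual,
        )
        return summary.to_dict()

    if cfg.mode == "government":
        gsol = solve_government(
            params, grid, opts_inner=opts, opts_outer=opts_outer
        )
        sol = gsol.solution
        summary = summarize(
            sol.traj, -gsol.V, duration_threshold=cfg.duration_threshold
        )
        write_trajectory_csv(
            outdir / "trajectory.csv", sol.traj, sol.costates, gsol.gov_costates
        )
        write_summary_json(
            outdir / "summary.json", summary, mode=cfg.mode, V=gsol.V,
            branch_label=gsol.branch_label,
        )
        _write_convergence(
            outdir, mode=cfg.mode, converged=gsol.converged,
            iterations=gsol.iterations, residual=gsol.residual,
        )
        return summary.to_dict()

    if cfg.mode == "scan":
        return _run_scan(cfg, params, grid, opts, opts_outer, outdir)

    raise ValueError(f"unknown mode {cfg.mode!r}")


def _run_scan(cfg, params, grid, opts, opts_outer, outdir: Path) -> dict:
    values = cfg.scan.values
    rows = []
    if cfg.scan.parameter == "alpha_g1":
        sols = branch_scan(
            params, values, grid=grid, opts_inner=opts, opts_outer=opts_outer
        )
        for a1, g in zip(values, sols):
            s = summarize(
                g.solution.traj, -g.V, duration_threshold=cfg.duration_threshold
            )
            rows.append(
                {
                    "alpha_g1": a1,
                    "peak_i": s.peak_i,
                    "total_cases": s.total_cases,
                    "duration": s.duration,
                    "V": g.V,
                    "branch": g.branch_label,
                    "n_local_optima": len(g.all_local_optima),
                    "converged": g.converged,
                }
            )
        switch = find_switch(values, sols)
    else:  # alpha1 scan of the Nash equilibrium
        for a1 in values:
            up = params.utility
            p = replace(
                params, utility=replace(up, cost=replace(up.cost, alpha1=a1))
            )
            sol = solve_nash(p, grid, opts=opts)
            s = summarize(
                sol.traj, -sol.objective, duration_threshold=cfg.duration_threshold
            )
            rows.append(
                {
                    "alpha1": a1,
                    "peak_i": s.peak_i,
                    "total_cases": s.total_cases,
                    "duration": s.duration,
                    "U": sol.objective,
                    "converged": sol.converged,
                }
            )
        switch = None
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "scan.csv", index=False)
    report = {"mode": "scan", "parameter": cfg.scan.parameter, "switch": switch}
    (outdir / "summary.json").write_text(json.dumps(report, indent=2) + "\n")
    _write_convergence(
        outdir, mode="scan", converged=bool(all(r["converged"] for r in rows))
    )
    return report


def make_figure_tables(outdirs: list[str | Path], dest: str | Path) -> pd.DataFrame:
    """Collate completed runs into one tidy per-scenario table (CSV).

    Each row is one run: scenario name, headline epidemic metrics, and the
    objective value — the layout the peak/total-cases/duration/cost panels
    are plotted from. Missing or incomplete run directories are reported.
    """
    rows = []
    missing = []
    for d in outdirs:
        d = Path(d)
        summ, confp = d / "summary.json", d / "config.json"
        if not summ.is_file() or not confp.is_file():
            missing.append(str(d))
            continue
        conf = json.loads(confp.read_text())
        row = {"scenario": conf.get("name", d.name), "mode": conf.get("mode")}
        row.update(json.loads(summ.read_text()))
        rows.append(row)
    if missing:
        raise FileNotFoundError(f"incomplete run directories: {', '.join(missing)}")
    df = pd.DataFrame(rows)
    df.to_csv(dest, index=False)
    return df
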