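"""Nash-equilibrium solver: costates, control rule, fixed point, audits."""

import numpy as np
import pytest

import epictrl as ec
from epictrl.nash import (
    best_response,
    control_update,
    individual_costates,
    individual_objective,
    solve_nash,
    terminal_costates,
)
from epictrl.epidemic import integrate_sir
from epictrl import _kernels


class TestIndividualCostates:
    def test_zero_cost_gives_zero_values(self, params_alpha0, grid, epidemic):
        traj = integrate_sir(np.full(grid.n, 4.0), epidemic, grid)
        cs = individual_costates(traj, params_alpha0.utility)
        assert np.allclose(cs.v_s, 0.0) and np.allclose(cs.v_i, 0.0)

    def test_no_epidemic_keeps_vs_at_zero(self, params_const400, grid):
        traj = ec.Trajectory(
            grid=grid, s=np.ones(grid.n), i=np.zeros(grid.n),
            k=np.full(grid.n, 4.0), eps=np.zeros(grid.n), kappa_star=4.0,
        )
        cs = individual_costates(traj, params_const400.utility)
        assert np.allclose(cs.v_s, 0.0)

    def test_terminal_conditions_exact(self, nash400, params_const400):
        vs_T, vi_T = terminal_costates(params_const400.utility, nash400.grid.tf)
        assert nash400.costates.v_s[-1] == vs_T
        assert nash400.costates.v_i[-1] == vi_T
        assert vi_T == pytest.approx(-400.0)  # f = 1, alpha(0) = 400

    def test_matches_refined_grid(self, params_const400, epidemic, nash400):
        """Backward integration agrees with a doubled-resolution solve."""
        g2 = ec.TimeGrid(tf=nash400.grid.tf, n=2 * nash400.grid.n - 1)
        k2 = np.interp(g2.nodes, nash400.grid.nodes, nash400.traj.k)
        traj2 = integrate_sir(k2, epidemic, g2)
        cs2 = individual_costates(traj2, params_const400.utility)
        scale = np.max(np.abs(nash400.costates.v_s))
        assert np.max(np.abs(cs2.v_i[::2] - nash400.costates.v_i)) < 1e-4
        assert np.max(np.abs(cs2.v_s[::2] - nash400.costates.v_s)) / scale < 1e-5

    def test_grid_mismatch_rejected(self, nash400, params_const400):
        other = ec.CostateTrajectory(
            grid=ec.TimeGrid(tf=50.0, n=11),
            v_s=np.zeros(11), v_i=np.zeros(11),
        )
        with pytest.raises(ValueError):
            control_update(nash400.traj, other, np.zeros(nash400.grid.n),
                           params_const400.utility)


class TestControlUpdate:
    def _traj(self, grid, s=0.5, i=0.1):
        return ec.Trajectory(
            grid=grid, s=np.full(grid.n, s), i=np.full(grid.n, i),
            k=np.full(grid.n, 4.0), eps=np.zeros(grid.n), kappa_star=4.0,
        )

    def test_equal_values_no_intervention(self, grid, params_const400):
        traj = self._traj(grid)
        cs = ec.CostateTrajectory(grid=grid, v_s=np.ones(grid.n), v_i=np.ones(grid.n))
        cand = control_update(traj, cs, np.zeros(grid.n), params_const400.utility)
        assert np.allclose(cand, 4.0)

    def test_intervention_shift(self, grid, params_const400):
        traj = self._traj(grid)
        cs = ec.CostateTrajectory(grid=grid, v_s=np.ones(grid.n), v_i=np.ones(grid.n))
        cand = control_update(traj, cs, np.full(grid.n, -2.0), params_const400.utility)
        assert np.allclose(cand, 3.0)  # kappa* + eps/2

    def test_clipped_at_zero(self, grid, params_const400):
        traj = self._traj(grid, s=1.0, i=1.0)
        # choose v_s - v_i so that the candidate is exactly -kappa* before clip
        cs = ec.CostateTrajectory(
            grid=grid, v_s=np.full(grid.n, 16.0), v_i=np.zeros(grid.n)
        )
        cand = control_update(traj, cs, np.zeros(grid.n), params_const400.utility)
        assert np.all(cand == 0.0)


class TestSolveNash:
    def test_no_risk_means_no_distancing(self, params_alpha0, grid):
        sol = solve_nash(params_alpha0, grid, auto_extend=False)
        assert sol.converged and sol.iterations == 1
        assert np.all(sol.traj.k == 4.0)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)

    def test_equilibrium_is_best_response_fixed_point(self, nash400, params_const400):
        rep = ec.verify_nash_fixed_point(nash400, params_const400)
        assert rep.gap < 1e-4
        assert rep.utility_gain < 1e-2  # no appreciable profitable defection

    def test_stationarity(self, nash400, params_const400):
        assert ec.pontryagin_residual(nash400, params_const400, "nash") < 1e-5

    def test_peak_decreases_with_infection_cost(self, epidemic, grid):
        peaks = []
        for alpha in (100.0, 175.0, 400.0):
            p = ec.ModelParams(
                epidemic=epidemic,
                utility=ec.UtilityParams(cost=ec.InfectionCostParams.const(alpha)),
            )
            sol = solve_nash(p, grid, auto_extend=False)
            assert sol.converged
            peaks.append(sol.traj.i.max())
        assert peaks[0] > peaks[1] > peaks[2]

    def test_objective_stable_under_grid_refinement(self, params_const400):
        vals = []
        for n in (4001, 8001):
            sol = solve_nash(params_const400, ec.TimeGrid(tf=100.0, n=n),
                             auto_extend=False)
            assert sol.converged
            vals.append(sol.objective)
        assert abs(vals[1] - vals[0]) / abs(vals[0]) < 1e-6

    def test_distancing_prolongs_but_dampens_epidemic(
        self, nash400, epidemic, fine_grid
    ):
        base = integrate_sir(np.full(fine_grid.n, 4.0), epidemic, fine_grid)
        s_n = ec.summarize(nash400.traj)
        s_b = ec.summarize(base)
        assert s_n.peak_i < s_b.peak_i
        assert s_n.total_cases < s_b.total_cases
        assert s_n.duration > s_b.duration


class TestBestResponse:
    def test_zero_cost_plays_baseline(self, params_alpha0, grid):
        kappa, u = best_response(np.full(grid.n, 3.0), params_alpha0, grid)
        assert np.max(np.abs(kappa - 4.0)) < 1e-6

    def test_defection_from_reckless_population(self, params_const400, grid, epidemic):
        """Against a no-distancing population, caution is profitable."""
        k_pop = np.full(grid.n, 4.0)
        kappa, u_br = best_response(k_pop, params_const400, grid)
        pop = integrate_sir(k_pop, epidemic, grid)
        ps, pi = _kernels.psi_forward(k_pop, pop.i, epidemic.s0, epidemic.i0, grid.dt)
        u_conform = individual_objective(k_pop, ps, pi, pop, params_const400.utility)
        assert np.max(np.abs(kappa - k_pop)) > 0.1
        assert u_br > u_conform

    def test_giveup_branch_exists(self, nash400, params_const400):
        """A second, less cautious stationary strategy coexists at consensus.

        Starting the defector's solve from the pre-epidemic baseline lands
        on the 'give-up' branch: near-baseline behaviour, early infection,
        and a (slightly) higher utility than conforming — the non-concavity
        that makes the computed equilibrium a first-order Nash point.
        """
        kappa, u = best_response(
            nash400.traj.k, params_const400, nash400.grid,
            init_kappa=np.full(nash400.grid.n, 4.0),
        )
        assert np.max(np.abs(kappa - nash400.traj.k)) > 0.5
        assert u > nash400.objective
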