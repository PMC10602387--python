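"""SIR integration, summary metrics, and the final-size oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import odeint

import epictrl as ec
from epictrl.epidemic import final_size_root, integrate_sir, summarize


def bisect_final_size(R0, s0, i0, iters=200):
    """Independent bisection oracle for s_inf = s0 exp(-R0 (s0 + i0 - s_inf))."""
    lo, hi = 1e-30, s0
    g = lambda x: x - s0 * np.exp(-R0 * (s0 + i0 - x))
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestIntegrateSIR:
    def test_uncontrolled_peak_near_analytic(self, epidemic, fine_grid):
        traj = integrate_sir(np.full(fine_grid.n, 4.0), epidemic, fine_grid)
        analytic = 1.0 - (1.0 + np.log(4.0)) / 4.0
        assert traj.i.max() == pytest.approx(analytic, abs=1e-4)

    def test_no_transmission_is_pure_decay(self, epidemic, grid):
        traj = integrate_sir(np.zeros(grid.n), epidemic, grid)
        assert np.allclose(traj.s, epidemic.s0, atol=1e-15)
        assert np.allclose(traj.i, epidemic.i0 * np.exp(-grid.nodes), rtol=1e-8)

    def test_final_size_matches_root(self, epidemic, fine_grid):
        traj = integrate_sir(np.full(fine_grid.n, 4.0), epidemic, fine_grid)
        s_inf = final_size_root(4.0, epidemic.s0, epidemic.i0)
        assert traj.i[-1] < 1e-8
        assert abs(traj.s[-1] - s_inf) < 1e-6

    def test_agrees_with_adaptive_lsoda(self, epidemic, fine_grid):
        """Cross-check the fixed-step scheme against an adaptive solver."""
        def rhs(y, t):
            s, i = y
            return [-4.0 * s * i, 4.0 * s * i - i]

        ref = odeint(
            rhs, [epidemic.s0, epidemic.i0], fine_grid.nodes,
            rtol=1e-11, atol=1e-14,
        )
        traj = integrate_sir(np.full(fine_grid.n, 4.0), epidemic, fine_grid)
        assert np.max(np.abs(traj.s - ref[:, 0])) < 2e-6
        assert np.max(np.abs(traj.i - ref[:, 1])) < 2e-6

    @pytest.mark.parametrize(
        "bad", [lambda n: -np.ones(n), lambda n: np.full(n, np.nan)]
    )
    def test_rejects_invalid_behaviour(self, bad, epidemic, grid):
        with pytest.raises(ValueError):
            integrate_sir(bad(grid.n), epidemic, grid)

    def test_grid_refinement_stability(self, epidemic):
        """Halving dt moves the solution path by less than 1e-6 everywhere."""
        g1 = ec.TimeGrid(tf=100.0, n=4001)
        g2 = ec.TimeGrid(tf=100.0, n=8001)
        i1 = integrate_sir(np.full(g1.n, 4.0), epidemic, g1).i
        i2 = integrate_sir(np.full(g2.n, 4.0), epidemic, g2).i
        assert np.max(np.abs(i1 - i2[::2])) < 1e-6

    @given(
        st.lists(st.floats(min_value=0.0, max_value=6.0), min_size=2, max_size=8)
    )
    def test_conservation_and_monotonicity(self, levels):
        """r = 1 - s - i never decreases; s never increases, for any k >= 0."""
        epidemic = ec.EpidemicParams(kappa_star=4.0, i0=1e-4)
        grid = ec.TimeGrid(tf=30.0, n=601)
        # piecewise-constant behaviour interpolated onto the grid
        k = np.repeat(levels, int(np.ceil(grid.n / len(levels))))[: grid.n]
        traj = integrate_sir(k, epidemic, grid)
        r = 1.0 - traj.s - traj.i
        assert np.all(np.diff(traj.s) <= 1e-12)
        assert np.all(np.diff(r) >= -1e-12)
        assert np.all(traj.s + traj.i <= 1.0 + 1e-9)
        # discrete conservation: d(s+i)/dt + i ~ 0
        dsum = np.gradient(traj.s + traj.i, grid.dt)
        mid = slice(1, -1)
        assert np.max(np.abs(dsum[mid] + traj.i[mid])) < 5e-3 * max(traj.i.max(), 1e-9)


class TestSummarize:
    def test_zero_epidemic(self, grid):
        traj = ec.Trajectory(
            grid=grid, s=np.ones(grid.n), i=np.zeros(grid.n),
            k=np.zeros(grid.n), eps=np.zeros(grid.n), kappa_star=4.0,
        )
        s = summarize(traj)
        assert s.duration == 0.0 and s.peak_i == 0.0

    def test_subthreshold_decay_has_zero_duration(self, epidemic, grid):
        traj = integrate_sir(np.zeros(grid.n), epidemic, grid)
        assert summarize(traj).duration == 0.0  # i0 = 3e-8 < 1e-4 always

    def test_duration_equals_node_count(self, epidemic, fine_grid):
        traj = integrate_sir(np.full(fine_grid.n, 4.0), epidemic, fine_grid)
        s = summarize(traj)
        expected = (traj.i > 1e-4).sum() * fine_grid.dt
        assert s.duration == pytest.approx(expected)
        assert s.total_cases == pytest.approx(1.0 - traj.s[-1])


class TestFinalSizeRoot:
    def test_subcritical_no_epidemic(self):
        assert final_size_root(0.9, s0=1.0 - 1e-12, i0=1e-12) == pytest.approx(
            1.0, abs=1e-6
        )

    @pytest.mark.parametrize(
        "R0,expected_attack",
        [(4.0, None), (2.0, 0.7968)],  # attack rate 1 - s_inf for s0 ~ 1
    )
    def test_matches_bisection_oracle(self, R0, expected_attack):
        s0, i0 = 1.0 - 3e-8, 3e-8
        root = final_size_root(R0, s0, i0)
        oracle = bisect_final_size(R0, s0, i0)
        assert root == pytest.approx(oracle, abs=1e-10)
        if expected_attack is not None:
            assert 1.0 - root == pytest.approx(expected_attack, abs=5e-4)

    def test_rejects_nonpositive_r0(self):
        with pytest.raises(ValueError):
            final_size_root(0.0)
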