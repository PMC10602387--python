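"""Infection-cost function, salvage terms, and objective evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import epictrl as ec
from epictrl.costs import (
    evaluate_objective,
    infection_cost,
    infection_cost_derivative,
    salvage_individual,
)
from epictrl.epidemic import integrate_sir

THRESH = ec.InfectionCostParams(alpha0=100.0, alpha1=400.0, i_hc=0.01, sigma=300.0)


class TestInfectionCost:
    def test_midpoint_at_threshold(self):
        p = ec.InfectionCostParams(alpha0=100.0, alpha1=400.0, i_hc=0.1, sigma=300.0)
        assert infection_cost(p.i_hc, p) == pytest.approx(250.0)

    @pytest.mark.parametrize(
        "i_hc,coeff",
        [(0.01, (1 - math.tanh(0.01 * 300)) / 2),
         (0.003, (1 - math.tanh(0.003 * 300)) / 2)],
    )
    def test_disease_free_tail_coefficient(self, i_hc, coeff):
        """α(0) = α0 + c (α1 − α0) with c = (1 − tanh(i_hc σ))/2."""
        p = ec.InfectionCostParams(alpha0=100.0, alpha1=400.0, i_hc=i_hc, sigma=300.0)
        c = (infection_cost(0.0, p) - p.alpha0) / (p.alpha1 - p.alpha0)
        assert c == pytest.approx(coeff, rel=1e-12)
        assert c == pytest.approx(p.alpha_at_zero() / (p.alpha1 - p.alpha0)
                                  - p.alpha0 / (p.alpha1 - p.alpha0), rel=1e-9)

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_and_bounded(self, i1, i2):
        lo, hi = sorted((i1, i2))
        assert infection_cost(lo, THRESH) <= infection_cost(hi, THRESH)
        # open interval mathematically; tanh saturates in float far from i_hc
        assert THRESH.alpha0 <= infection_cost(lo, THRESH) <= THRESH.alpha1
        if lo <= THRESH.i_hc + 15.0 / THRESH.sigma:  # before float saturation
            assert THRESH.alpha0 < infection_cost(lo, THRESH) < THRESH.alpha1

    def test_constant_variant(self):
        p = ec.InfectionCostParams.const(42.0)
        assert infection_cost(0.5, p) == 42.0
        assert infection_cost_derivative(0.5, p) == 0.0


class TestDerivative:
    def test_peak_value_at_threshold(self):
        assert infection_cost_derivative(THRESH.i_hc, THRESH) == pytest.approx(
            0.5 * (THRESH.alpha1 - THRESH.alpha0) * THRESH.sigma
        )

    @pytest.mark.parametrize("i", [0.0, 0.005, 0.01, 0.01 + 5 / 300.0, 0.2])
    def test_matches_finite_difference(self, i):
        h = 1e-6
        fd = (infection_cost(i + h, THRESH) - infection_cost(i - h, THRESH)) / (2 * h)
        assert infection_cost_derivative(i, THRESH) == pytest.approx(fd, rel=1e-6)

    def test_vanishes_far_from_threshold(self):
        d = infection_cost_derivative(1.0, THRESH)
        assert np.isfinite(d) and 0.0 <= d < 1e-100


class TestSalvage:
    def test_undiscounted_limit(self):
        p = ec.InfectionCostParams.const(400.0)
        assert salvage_individual(1e-8, 1.0, 100.0, p) == pytest.approx(-400.0 * 1e-8)
        assert salvage_individual(0.0, 1.0, 100.0, p) == 0.0

    @pytest.mark.parametrize("f", [1.0, 1.05])
    def test_matches_tail_quadrature(self, f):
        """Closed form vs numerical integral of the post-horizon tail.

        After tf the epidemic is burnt out: i(t) = i_f e^(−(t−tf)) and the
        tail utility is −∫_tf^∞ f^(−t) α(0) i(t) dt.
        """
        p = ec.InfectionCostParams.const(400.0)
        tf, i_f = 60.0, 1e-8
        integrand = lambda t: f ** (-t) * p.alpha0 * i_f * math.exp(-(t - tf))
        tail, _ = quad(integrand, tf, np.inf, epsabs=1e-18, epsrel=1e-12)
        closed = salvage_individual(i_f, f, tf, p)
        assert closed == pytest.approx(-tail, rel=1e-6)


class TestEvaluateObjective:
    def _gov(self):
        return ec.GovernmentParams(
            cost_g=ec.InfectionCostParams.const(400.0), gamma_g=0.5
        )

    def test_zero_epidemic_all_objectives_vanish(self, grid):
        up = ec.UtilityParams(cost=ec.InfectionCostParams.const(400.0))
        traj = ec.Trajectory(
            grid=grid, s=np.ones(grid.n), i=np.zeros(grid.n),
            k=np.full(grid.n, 4.0), eps=np.zeros(grid.n), kappa_star=4.0,
        )
        for which in ("individual", "population", "government"):
            assert evaluate_objective(traj, which, up, self._gov()) == 0.0

    def test_baseline_matches_quadrature_oracle(self, epidemic):
        """Constant-α objective on the k ≡ κ* baseline vs refined-grid quadrature."""
        up = ec.UtilityParams(cost=ec.InfectionCostParams.const(400.0))
        vals = []
        for n in (4001, 16001):
            g = ec.TimeGrid(tf=100.0, n=n)
            traj = integrate_sir(np.full(g.n, 4.0), epidemic, g)
            vals.append(evaluate_objective(traj, "population", up))
        # distancing and intervention terms vanish; value is -400 ∫ i dt + tail
        assert vals[0] == pytest.approx(vals[1], rel=1e-7)
        g = ec.TimeGrid(tf=100.0, n=16001)
        traj = integrate_sir(np.full(g.n, 4.0), epidemic, g)
        direct = -400.0 * np.trapezoid(traj.i, dx=g.dt) + salvage_individual(
            float(traj.i[-1]), 1.0, g.tf, up.cost
        )
        assert vals[1] == pytest.approx(direct, rel=1e-12)

    def test_unknown_objective_rejected(self, grid):
        up = ec.UtilityParams(cost=ec.InfectionCostParams.const(1.0))
        traj = ec.Trajectory(
            grid=grid, s=np.ones(grid.n), i=np.zeros(grid.n),
            k=np.zeros(grid.n), eps=np.zeros(grid.n), kappa_star=4.0,
        )
        with pytest.raises(ValueError):
            evaluate_objective(traj, "galactic", up)
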