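"""Shared fixtures: parameter sets and (session-cached) converged solves."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import epictrl as ec
from epictrl.sweep import SweepOptions

warnings.filterwarnings("ignore", message="overflow")

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def epidemic():
    return ec.EpidemicParams()  # kappa* = 4, i0 = 3e-8


@pytest.fixture(scope="session")
def grid():
    # dt = 0.05: fast enough for the full suite, converged for every check
    # that does not itself probe grid refinement
    return ec.TimeGrid(tf=100.0, n=2001)


@pytest.fixture(scope="session")
def fine_grid():
    return ec.TimeGrid(tf=100.0, n=4001)


@pytest.fixture(scope="session")
def params_const400(epidemic):
    return ec.ModelParams(
        epidemic=epidemic,
        utility=ec.UtilityParams(cost=ec.InfectionCostParams.const(400.0)),
    )


@pytest.fixture(scope="session")
def params_alpha0(epidemic):
    return ec.ModelParams(
        epidemic=epidemic,
        utility=ec.UtilityParams(cost=ec.InfectionCostParams.const(0.0)),
    )


@pytest.fixture(scope="session")
def params_fig3(epidemic):
    return ec.ModelParams(
        epidemic=epidemic,
        utility=ec.UtilityParams(
            cost=ec.InfectionCostParams(
                alpha0=100.0, alpha1=400.0, i_hc=0.1, sigma=300.0
            )
        ),
    )


@pytest.fixture(scope="session")
def params_gov_matched(epidemic):
    cost = ec.InfectionCostParams.const(400.0)
    return ec.ModelParams(
        epidemic=epidemic,
        utility=ec.UtilityParams(cost=cost),
        government=ec.GovernmentParams(cost_g=cost, gamma_g=0.0),
    )


@pytest.fixture(scope="session")
def nash400(params_const400, fine_grid):
    sol = ec.solve_nash(params_const400, fine_grid, auto_extend=False)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def util400(params_const400, fine_grid):
    sol = ec.solve_utilitarian(params_const400, fine_grid, auto_extend=False)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def nash_fig3(params_fig3, grid):
    sol = ec.solve_nash(params_fig3, grid, auto_extend=False)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def util_fig3(params_fig3, grid):
    return ec.solve_utilitarian(params_fig3, grid, auto_extend=False)


@pytest.fixture(scope="session")
def gov_matched(params_gov_matched, fine_grid):
    # the matched cost-free intervention problem on the fine grid; the
    # induced behaviour must coincide with the utilitarian optimum
    sol = ec.solve_government(params_gov_matched, fine_grid, auto_extend=False)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def util_matched_fine(params_gov_matched, fine_grid):
    sol = ec.solve_utilitarian(params_gov_matched, fine_grid, auto_extend=False)
    assert sol.converged
    return sol
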