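"""Compiled fixed-step RK4 integrators for states and costates.

Every pass here is a classical 4th-order Runge-Kutta march on the shared
uniform grid. Node-valued controls and exogenous paths are treated as
piecewise linear: the mid-step stages use the average of the two bracketing
node values. Backward (costate) passes use exactly the same stencil run in
reverse so forward and backward discretizations match, which is what keeps
the forward-backward sweep's fixed point consistent with the discrete
optimality conditions.

Infection-cost parameters are passed as scalars (a0, a1, ihc, sig, const)
rather than objects so the kernels stay in nopython mode.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "sir_forward",
    "psi_forward",
    "psi_forward_coupled",
    "costates_backward",
    "gov_costates_backward",
]


@njit(cache=True, fastmath=False)
def _alpha(i, a0, a1, ihc, sig, const):
    if const:
        return a0
    return a0 + 0.5 * (a1 - a0) * (np.tanh((i - ihc) * sig) + 1.0)


@njit(cache=True, fastmath=False)
def _alpha_prime(i, a0, a1, ihc, sig, const):
    if const:
        return 0.0
    c = np.cosh((i - ihc) * sig)
    return 0.5 * (a1 - a0) * sig / (c * c)


@njit(cache=True, fastmath=False)
def sir_forward(k, s0, i0, dt):
    """March s' = -k s i, i' = k s i - i from (s0, i0) along node path k."""
    n = k.shape[0]
    s = np.empty(n)
    i = np.empty(n)
    s[0] = s0
    i[0] = i0
    for j in range(n - 1):
        ka = k[j]
        kb = k[j + 1]
        km = 0.5 * (ka + kb)
        sj = s[j]
        ij = i[j]

        ds1 = -ka * sj * ij
        di1 = ka * sj * ij - ij
        s2 = sj + 0.5 * dt * ds1
        i2 = ij + 0.5 * dt * di1
        ds2 = -km * s2 * i2
        di2 = km * s2 * i2 - i2
        s3 = sj + 0.5 * dt * ds2
        i3 = ij + 0.5 * dt * di2
        ds3 = -km * s3 * i3
        di3 = km * s3 * i3 - i3
        s4 = sj + dt * ds3
        i4 = ij + dt * di3
        ds4 = -kb * s4 * i4
        di4 = kb * s4 * i4 - i4

        s[j + 1] = sj + dt / 6.0 * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4)
        i[j + 1] = ij + dt / 6.0 * (di1 + 2.0 * di2 + 2.0 * di3 + di4)
    return s, i


@njit(cache=True, fastmath=False)
def psi_forward(kappa, ipop, psi_s0, psi_i0, dt):
    """Individual compartment probabilities against an exogenous epidemic.

    ψ_s' = -κ ψ_s i,  ψ_i' = κ ψ_s i - ψ_i, where i is the (frozen)
    population infected path.
    """
    n = kappa.shape[0]
    ps = np.empty(n)
    pi = np.empty(n)
    ps[0] = psi_s0
    pi[0] = psi_i0
    for j in range(n - 1):
        ka = kappa[j]
        kb = kappa[j + 1]
        km = 0.5 * (ka + kb)
        ia = ipop[j]
        ib = ipop[j + 1]
        im = 0.5 * (ia + ib)
        pj = ps[j]
        qj = pi[j]

        d1s = -ka * pj * ia
        d1i = ka * pj * ia - qj
        p2 = pj + 0.5 * dt * d1s
        q2 = qj + 0.5 * dt * d1i
        d2s = -km * p2 * im
        d2i = km * p2 * im - q2
        p3 = pj + 0.5 * dt * d2s
        q3 = qj + 0.5 * dt * d2i
        d3s = -km * p3 * im
        d3i = km * p3 * im - q3
        p4 = pj + dt * d3s
        q4 = qj + dt * d3i
        d4s = -kb * p4 * ib
        d4i = kb * p4 * ib - q4

        ps[j + 1] = pj + dt / 6.0 * (d1s + 2.0 * d2s + 2.0 * d3s + d4s)
        pi[j + 1] = qj + dt / 6.0 * (d1i + 2.0 * d2i + 2.0 * d3i + d4i)
    return ps, pi


@njit(cache=True, fastmath=False)
def psi_forward_coupled(
    vs, vi, ipop, eps, s0_, i0_, kstar, lnf, beta, dt, t0
):
    """Individual probabilities with the control eliminated inside the pass.

    At every RK4 stage the behaviour is the pointwise optimum

        κ = max(0, κ* − f^t/2 (v_s − v_i) ψ_s i / β + ε/(2β))

    evaluated with the *local* stage ψ_s, so the (destabilising) dependence
    of the optimal control on the individual's own susceptibility is resolved
    algebraically within the forward integration rather than iterated.
    Returns (ψ_s, ψ_i, κ at the nodes).
    """
    n = ipop.shape[0]
    ps = np.empty(n)
    pi = np.empty(n)
    kap = np.empty(n)
    ps[0] = s0_
    pi[0] = i0_
    for j in range(n - 1):
        tj = t0 + j * dt
        tm = tj + 0.5 * dt
        tb = tj + dt
        ia = ipop[j]
        ib = ipop[j + 1]
        im = 0.5 * (ia + ib)
        dva = vs[j] - vi[j]
        dvb = vs[j + 1] - vi[j + 1]
        dvm = 0.5 * (dva + dvb)
        ea = eps[j]
        eb = eps[j + 1]
        em = 0.5 * (ea + eb)
        fa = np.exp(tj * lnf)
        fm = np.exp(tm * lnf)
        fb = np.exp(tb * lnf)
        pj = ps[j]
        qj = pi[j]

        k1 = max(0.0, kstar - 0.5 * fa * dva * pj * ia / beta + 0.5 * ea / beta)
        if j == 0:
            kap[0] = k1
        d1s = -k1 * pj * ia
        d1i = k1 * pj * ia - qj
        p2 = pj + 0.5 * dt * d1s
        q2 = qj + 0.5 * dt * d1i
        k2 = max(0.0, kstar - 0.5 * fm * dvm * p2 * im / beta + 0.5 * em / beta)
        d2s = -k2 * p2 * im
        d2i = k2 * p2 * im - q2
        p3 = pj + 0.5 * dt * d2s
        q3 = qj + 0.5 * dt * d2i
        k3 = max(0.0, kstar - 0.5 * fm * dvm * p3 * im / beta + 0.5 * em / beta)
        d3s = -k3 * p3 * im
        d3i = k3 * p3 * im - q3
        p4 = pj + dt * d3s
        q4 = qj + dt * d3i
        k4 = max(0.0, kstar - 0.5 * fb * dvb * p4 * ib / beta + 0.5 * eb / beta)
        d4s = -k4 * p4 * ib
        d4i = k4 * p4 * ib - q4

        ps[j + 1] = pj + dt / 6.0 * (d1s + 2.0 * d2s + 2.0 * d3s + d4s)
        pi[j + 1] = qj + dt / 6.0 * (d1i + 2.0 * d2i + 2.0 * d3i + d4i)
        kap[j + 1] = max(
            0.0,
            kstar - 0.5 * fb * dvb * ps[j + 1] * ib / beta + 0.5 * eb / beta,
        )
    return ps, pi, kap


@njit(cache=True, fastmath=False)
def costates_backward(
    kappa,
    s,
    i,
    dt,
    t0,
    lnf,
    a0,
    a1,
    ihc,
    sig,
    const,
    vs_T,
    vi_T,
    population,
):
    """Backward march of the individual or population costate equations.

    Individual (``population=False``; the marginal values of the individual's
    own susceptible/infectious probabilities):

        v_s' = (v_s - v_i) κ i
        v_i' = f^(-t) α(i) + v_i

    Population (``population=True``; Lagrange multipliers of the coordinated
    problem) gains the externality terms:

        v_i' += f^(-t) α'(i) i + (v_s - v_i) k s

    Terminal values (vs_T, vi_T) are imposed at the last node.
    """
    n = kappa.shape[0]
    vs = np.empty(n)
    vi = np.empty(n)
    vs[n - 1] = vs_T
    vi[n - 1] = vi_T
    h = -dt
    for j in range(n - 1, 0, -1):
        tj = t0 + j * dt
        ka = kappa[j]
        kb = kappa[j - 1]
        km = 0.5 * (ka + kb)
        ia = i[j]
        ib = i[j - 1]
        im = 0.5 * (ia + ib)
        sa = s[j]
        sb = s[j - 1]
        sm = 0.5 * (sa + sb)
        va = vs[j]
        wa = vi[j]

        # stage 1 at t_j
        disc = np.exp(-tj * lnf)
        d1s = (va - wa) * ka * ia
        d1i = disc * _alpha(ia, a0, a1, ihc, sig, const) + wa
        if population:
            d1i += disc * _alpha_prime(ia, a0, a1, ihc, sig, const) * ia
            d1i += (va - wa) * ka * sa

        tm = tj - 0.5 * dt
        discm = np.exp(-tm * lnf)
        v2 = va + 0.5 * h * d1s
        w2 = wa + 0.5 * h * d1i
        d2s = (v2 - w2) * km * im
        d2i = discm * _alpha(im, a0, a1, ihc, sig, const) + w2
        if population:
            d2i += discm * _alpha_prime(im, a0, a1, ihc, sig, const) * im
            d2i += (v2 - w2) * km * sm

        v3 = va + 0.5 * h * d2s
        w3 = wa + 0.5 * h * d2i
        d3s = (v3 - w3) * km * im
        d3i = discm * _alpha(im, a0, a1, ihc, sig, const) + w3
        if population:
            d3i += discm * _alpha_prime(im, a0, a1, ihc, sig, const) * im
            d3i += (v3 - w3) * km * sm

        tb = tj - dt
        discb = np.exp(-tb * lnf)
        v4 = va + h * d3s
        w4 = wa + h * d3i
        d4s = (v4 - w4) * kb * ib
        d4i = discb * _alpha(ib, a0, a1, ihc, sig, const) + w4
        if population:
            d4i += discb * _alpha_prime(ib, a0, a1, ihc, sig, const) * ib
            d4i += (v4 - w4) * kb * sb

        vs[j - 1] = va + h / 6.0 * (d1s + 2.0 * d2s + 2.0 * d3s + d4s)
        vi[j - 1] = wa + h / 6.0 * (d1i + 2.0 * d2i + 2.0 * d3i + d4i)
    return vs, vi


@njit(cache=True, fastmath=False)
def _gov_rates(
    t,
    s,
    i,
    eps,
    vs,
    vi,
    ls,
    li,
    lnf,
    lnfg,
    kstar,
    betag,
    gammag,
    a0,
    a1,
    ihc,
    sig,
    const,
):
    """Right-hand side (λ_s', λ_i', Λ) of the government costate system."""
    dfg = np.exp(-t * lnfg)
    ft = np.exp(t * lnf)
    fgt = np.exp(t * lnfg)
    lam = -(li - ls) * (kstar + 0.5 * eps) + dfg * 0.5 * ft * (vi - vs) * (
        i * s * (betag * ft * (vi - vs) - 2.0 * fgt * (li - ls))
        + eps * (gammag + betag)
    )
    dls = i * lam
    dli = (
        s * lam
        + dfg
        * (
            _alpha(i, a0, a1, ihc, sig, const)
            + _alpha_prime(i, a0, a1, ihc, sig, const) * i
        )
        + li
    )
    return dls, dli, lam


@njit(cache=True, fastmath=False)
def gov_costates_backward(
    s,
    i,
    eps,
    vs,
    vi,
    dt,
    t0,
    lnf,
    lnfg,
    kstar,
    betag,
    gammag,
    a0,
    a1,
    ihc,
    sig,
    const,
    ls_T,
    li_T,
):
    """Backward march of the government costates (λ_s, λ_i) and Λ diagnostic.

    The inner equilibrium's costates (vs, vi) and the intervention path eps
    enter as exogenous node paths; the infection-cost scalars are the
    *government's* (α_g). Returns (λ_s, λ_i, Λ) with Λ evaluated at the nodes.
    """
    n = s.shape[0]
    ls = np.empty(n)
    li = np.empty(n)
    lam_out = np.empty(n)
    ls[n - 1] = ls_T
    li[n - 1] = li_T
    h = -dt
    for j in range(n - 1, 0, -1):
        tj = t0 + j * dt
        tm = tj - 0.5 * dt
        tb = tj - dt
        sm = 0.5 * (s[j] + s[j - 1])
        im = 0.5 * (i[j] + i[j - 1])
        em = 0.5 * (eps[j] + eps[j - 1])
        vsm = 0.5 * (vs[j] + vs[j - 1])
        vim = 0.5 * (vi[j] + vi[j - 1])
        la = ls[j]
        lb = li[j]

        d1s, d1i, lam1 = _gov_rates(
            tj, s[j], i[j], eps[j], vs[j], vi[j], la, lb,
            lnf, lnfg, kstar, betag, gammag, a0, a1, ihc, sig, const,
        )
        if j == n - 1:
            lam_out[j] = lam1
        d2s, d2i, _ = _gov_rates(
            tm, sm, im, em, vsm, vim, la + 0.5 * h * d1s, lb + 0.5 * h * d1i,
            lnf, lnfg, kstar, betag, gammag, a0, a1, ihc, sig, const,
        )
        d3s, d3i, _ = _gov_rates(
            tm, sm, im, em, vsm, vim, la + 0.5 * h * d2s, lb + 0.5 * h * d2i,
            lnf, lnfg, kstar, betag, gammag, a0, a1, ihc, sig, const,
        )
        d4s, d4i, _ = _gov_rates(
            tb, s[j - 1], i[j - 1], eps[j - 1], vs[j - 1], vi[j - 1],
            la + h * d3s, lb + h * d3i,
            lnf, lnfg, kstar, betag, gammag, a0, a1, ihc, sig, const,
        )
        ls[j - 1] = la + h / 6.0 * (d1s + 2.0 * d2s + 2.0 * d3s + d4s)
        li[j - 1] = lb + h / 6.0 * (d1i + 2.0 * d2i + 2.0 * d3i + d4i)
        _, _, lamb = _gov_rates(
            tb, s[j - 1], i[j - 1], eps[j - 1], vs[j - 1], vi[j - 1],
            ls[j - 1], li[j - 1],
            lnf, lnfg, kstar, betag, gammag, a0, a1, ihc, sig, const,
        )
        lam_out[j - 1] = lamb
    return ls, li, lam_out
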