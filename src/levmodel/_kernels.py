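"""Numba-compiled fixed-step RK4 integrators.

These kernels are the hot path of both the simulator and the
variational-Laplace objective (which re-integrates the model for every
finite-difference Jacobian column).  They are deliberately plain loops over
float64 arrays; all model structure lives in the typed wrappers of the
public modules.

Input series are treated as piecewise linear between grid nodes (RK4 half
steps use the midpoint average).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# consts layout for the electrical kernels:
# 0 tau_m, 1 r_in, 2 r_soma, 3 r_basal, 4 r_apical,
# 5 r_axial_basal, 6 r_axial_apical, 7 in_vbar, 8 in_r, 9 w_pc_fb


@njit(cache=False)
def _sig(v, vbar, r):
    return 1.0 / (1.0 + np.exp(-r * (v - vbar)))


@njit(cache=False)
def electrical_rhs(x, p1, p2, p3, gaba, pc_vbar, pc_r, c, out):
    tau = c[0]
    th1 = _sig(x[0], c[7], c[8]) - _sig(0.0, c[7], c[8])
    th2 = _sig(x[1], c[7], c[8]) - _sig(0.0, c[7], c[8])
    thp = _sig(x[2], pc_vbar, pc_r) - _sig(0.0, pc_vbar, pc_r)
    i_ax_b = (x[3] - x[2]) / c[5]
    i_ax_a = (x[4] - x[2]) / c[6]
    out[0] = (-x[0] + c[1] * p1) / tau
    out[1] = (-x[1] + c[1] * c[9] * thp) / tau
    out[2] = (-x[2] + c[2] * (-gaba * (th1 + th2) + i_ax_b + i_ax_a)) / tau
    out[3] = (-x[3] + c[3] * (p2 - i_ax_b)) / tau
    out[4] = (-x[4] + c[4] * (p3 - i_ax_a)) / tau


@njit(cache=False)
def integrate_electrical(a1, a2, a3, x0, gaba, pc_vbar, pc_r, c, dt):
    n = a1.shape[0]
    states = np.empty((n, 5))
    derivs = np.empty((n, 5))
    x = x0.copy()
    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    xt = np.empty(5)
    for i in range(n - 1):
        states[i] = x
        p1a, p2a, p3a = a1[i], a2[i], a3[i]
        p1b, p2b, p3b = a1[i + 1], a2[i + 1], a3[i + 1]
        p1m = 0.5 * (p1a + p1b)
        p2m = 0.5 * (p2a + p2b)
        p3m = 0.5 * (p3a + p3b)
        electrical_rhs(x, p1a, p2a, p3a, gaba, pc_vbar, pc_r, c, k1)
        derivs[i] = k1
        for j in range(5):
            xt[j] = x[j] + 0.5 * dt * k1[j]
        electrical_rhs(xt, p1m, p2m, p3m, gaba, pc_vbar, pc_r, c, k2)
        for j in range(5):
            xt[j] = x[j] + 0.5 * dt * k2[j]
        electrical_rhs(xt, p1m, p2m, p3m, gaba, pc_vbar, pc_r, c, k3)
        for j in range(5):
            xt[j] = x[j] + dt * k3[j]
        electrical_rhs(xt, p1b, p2b, p3b, gaba, pc_vbar, pc_r, c, k4)
        for j in range(5):
            x[j] = x[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    states[n - 1] = x
    electrical_rhs(x, a1[n - 1], a2[n - 1], a3[n - 1],
                   gaba, pc_vbar, pc_r, c, k1)
    derivs[n - 1] = k1
    return states, derivs


@njit(cache=False)
def lowpass_second_order(x, dt, gain, cutoff, damping, u0, du0):
    """Canonical second-order low-pass driven by a sampled series.

    Solves u'' + 2*damping*cutoff*u' + cutoff^2*u = gain*cutoff^2*x(t)
    with RK4 on the sampling grid of ``x``; returns (u, u').
    """
    n = x.shape[0]
    u = np.empty(n)
    du = np.empty(n)
    w2 = cutoff * cutoff
    a, b = u0, du0
    for i in range(n - 1):
        u[i] = a
        du[i] = b
        xa = x[i]
        xb = x[i + 1]
        xm = 0.5 * (xa + xb)
        # k1
        k1a = b
        k1b = gain * w2 * xa - 2.0 * damping * cutoff * b - w2 * a
        # k2
        a2_ = a + 0.5 * dt * k1a
        b2_ = b + 0.5 * dt * k1b
        k2a = b2_
        k2b = gain * w2 * xm - 2.0 * damping * cutoff * b2_ - w2 * a2_
        # k3
        a3_ = a + 0.5 * dt * k2a
        b3_ = b + 0.5 * dt * k2b
        k3a = b3_
        k3b = gain * w2 * xm - 2.0 * damping * cutoff * b3_ - w2 * a3_
        # k4
        a4_ = a + dt * k3a
        b4_ = b + dt * k3b
        k4a = b4_
        k4b = gain * w2 * xb - 2.0 * damping * cutoff * b4_ - w2 * a4_
        a = a + dt / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        b = b + dt / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
    u[n - 1] = a
    du[n - 1] = b
    return u, du


@njit(cache=False)
def _u_at(u, dt_u, t, n):
    """Piecewise-linear value of drive series u at time t (clamped)."""
    s = t / dt_u
    i = int(s)
    if i < 0:
        return u[0]
    if i >= n - 1:
        return u[n - 1]
    w = s - i
    return (1.0 - w) * u[i] + w * u[i + 1]


@njit(cache=False)
def _balloon_rhs(x, uval, kappa, gamma, tau, alpha, e0, out):
    # x = (s, log f, log v, log q); log states keep f, v, q positive
    s = x[0]
    f = np.exp(x[1])
    v = np.exp(x[2])
    q = np.exp(x[3])
    fout = v ** (1.0 / alpha)
    e_f = 1.0 - (1.0 - e0) ** (1.0 / f)
    out[0] = uval - kappa * s - gamma * (f - 1.0)
    out[1] = s / f
    out[2] = (f - fout) / (tau * v)
    out[3] = (f * e_f / e0 - fout * q / v) / (tau * q)


@njit(cache=False)
def integrate_balloon(u, dt_u, dt, n_out, kappa, gamma, tau, alpha, e0, x0):
    """Integrate the extended Balloon model under drive ``u``.

    ``u`` is sampled at ``dt_u``; the integrator runs at ``dt`` for
    ``n_out`` nodes.  ``x0 = (s, log f, log v, log q)``.  Returns an
    (n_out, 4) array of (s, f, v, q) with the log states exponentiated.
    """
    nu = u.shape[0]
    out = np.empty((n_out, 4))
    x = x0.copy()
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    xt = np.empty(4)
    for i in range(n_out):
        out[i, 0] = x[0]
        out[i, 1] = np.exp(x[1])
        out[i, 2] = np.exp(x[2])
        out[i, 3] = np.exp(x[3])
        if i == n_out - 1:
            break
        t = i * dt
        ua = _u_at(u, dt_u, t, nu)
        um = _u_at(u, dt_u, t + 0.5 * dt, nu)
        ub = _u_at(u, dt_u, t + dt, nu)
        _balloon_rhs(x, ua, kappa, gamma, tau, alpha, e0, k1)
        for j in range(4):
            xt[j] = x[j] + 0.5 * dt * k1[j]
        _balloon_rhs(xt, um, kappa, gamma, tau, alpha, e0, k2)
        for j in range(4):
            xt[j] = x[j] + 0.5 * dt * k2[j]
        _balloon_rhs(xt, um, kappa, gamma, tau, alpha, e0, k3)
        for j in range(4):
            xt[j] = x[j] + dt * k3[j]
        _balloon_rhs(xt, ub, kappa, gamma, tau, alpha, e0, k4)
        for j in range(4):
            x[j] = x[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    return out
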