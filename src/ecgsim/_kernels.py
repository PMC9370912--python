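"""Compiled fixed-step RK4 loops for the four models.

These are the production integration paths; :mod:`ecgsim.models` holds the
readable reference derivatives, and the two are cross-checked in the test
suite.  Delayed quantities are looked up once at the start of each step and
held frozen through the four Runge-Kutta stages, matching the sample-buffer
strategy of a fixed-step real-time solver.  History before t0 is the
constant initial state.

Every loop returns ``(hist, n_done)`` where ``hist`` has shape
``(n + 1, dim)``; ``n_done < n + 1`` signals that the state turned
non-finite at row ``n_done``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["het_loop", "rd_loop", "ring_loop", "qp_loop"]


@njit(cache=True)
def _het_deriv(s, t, dy_av, dy_hp,
               pa, pu, pf, pd, pe, pK,
               mk, mc, mw1, mw2, mb, mg, mh, mC, out):
    for i in range(3):
        x = s[2 * i]
        y = s[2 * i + 1]
        dy = -pa[i] * (x * x - pu[i]) * y - pf[i] * x * (x + pd[i]) * (x + pe[i])
        if i == 1:
            dy += pK[1] * (dy_av - y)
        elif i == 2:
            dy += pK[2] * (dy_hp - y)
        out[2 * i] = y
        out[2 * i + 1] = dy
    y1 = s[1]
    y3 = s[5]
    for j in range(4):
        if j == 0:
            Yj = y1
        elif j == 1:
            Yj = -y1
        elif j == 2:
            Yj = y3
        else:
            Yj = -y3
        current = mC[j] * Yj if Yj > 0.0 else 0.0
        z = s[6 + 2 * j]
        v = s[7 + 2 * j]
        out[6 + 2 * j] = mk[j] * (-mc[j] * z * (z - mw1[j]) * (z - mw2[j])
                                  - mb[j] * v - mg[j] * v * z + current)
        out[7 + 2 * j] = mk[j] * mh[j] * (z - v)


@njit(cache=True)
def het_loop(x0, n, h, pa, pu, pf, pd, pe, pK, off_av, off_hp,
             mk, mc, mw1, mw2, mb, mg, mh, mC):
    dim = 14
    hist = np.empty((n + 1, dim))
    hist[0] = x0
    s = x0.copy()
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    tmp = np.empty(dim)
    for i in range(n):
        t = i * h
        j = i - off_av
        dy_av = hist[j, 1] if j >= 0 else hist[0, 1]
        j = i - off_hp
        dy_hp = hist[j, 3] if j >= 0 else hist[0, 3]
        _het_deriv(s, t, dy_av, dy_hp, pa, pu, pf, pd, pe, pK,
                   mk, mc, mw1, mw2, mb, mg, mh, mC, k1)
        for m in range(dim):
            tmp[m] = s[m] + 0.5 * h * k1[m]
        _het_deriv(tmp, t + 0.5 * h, dy_av, dy_hp, pa, pu, pf, pd, pe, pK,
                   mk, mc, mw1, mw2, mb, mg, mh, mC, k2)
        for m in range(dim):
            tmp[m] = s[m] + 0.5 * h * k2[m]
        _het_deriv(tmp, t + 0.5 * h, dy_av, dy_hp, pa, pu, pf, pd, pe, pK,
                   mk, mc, mw1, mw2, mb, mg, mh, mC, k3)
        for m in range(dim):
            tmp[m] = s[m] + h * k3[m]
        _het_deriv(tmp, t + h, dy_av, dy_hp, pa, pu, pf, pd, pe, pK,
                   mk, mc, mw1, mw2, mb, mg, mh, mC, k4)
        ok = True
        for m in range(dim):
            s[m] = s[m] + (h / 6.0) * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
            if not np.isfinite(s[m]):
                ok = False
        hist[i + 1] = s
        if not ok:
            return hist, i + 1
    return hist, n + 1


@njit(cache=True)
def _rd_deriv(s, H, C, beta, out):
    x1 = s[0]
    x2 = s[1]
    x3 = s[2]
    x4 = s[3]
    out[0] = x1 - x2 - C * x1 * x2 - x1 * x2 * x2
    out[1] = H * x1 - 3.0 * x2 + C * x1 * x2 + x1 * x2 * x2 + beta * (x4 - x2)
    out[2] = x3 - x4 - C * x3 * x4 - x3 * x4 * x4
    out[3] = H * x3 - 3.0 * x4 + C * x3 * x4 + x3 * x4 * x4 + 2.0 * beta * (x2 - x4)


@njit(cache=True)
def rd_loop(x0, n, h, H, C, beta):
    dim = 4
    hist = np.empty((n + 1, dim))
    hist[0] = x0
    s = x0.copy()
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    tmp = np.empty(dim)
    for i in range(n):
        _rd_deriv(s, H, C, beta, k1)
        for m in range(dim):
            tmp[m] = s[m] + 0.5 * h * k1[m]
        _rd_deriv(tmp, H, C, beta, k2)
        for m in range(dim):
            tmp[m] = s[m] + 0.5 * h * k2[m]
        _rd_deriv(tmp, H, C, beta, k3)
        for m in range(dim):
            tmp[m] = s[m] + h * k3[m]
        _rd_deriv(tmp, H, C, beta, k4)
        ok = True
        for m in range(dim):
            s[m] = s[m] + (h / 6.0) * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
            if not np.isfinite(s[m]):
                ok = False
        hist[i + 1] = s
        if not ok:
            return hist, i + 1
    return hist, n + 1


@njit(cache=True)
def _ring_deriv(s, t, a, w1, w2, d, e, rho, om, kk, dval, out):
    for node in range(3):
        pos = s[2 * node]
        vel = s[2 * node + 1]
        acc = (-a[node] * vel * (pos - w1[node]) * (pos - w2[node])
               + rho[node] * math.sin(om[node] * t)
               - pos * (pos - d[node]) * (pos - e[node]))
        c0 = 2 * node
        if kk[c0] != 0.0:
            acc -= kk[c0] * (pos - dval[c0])
        if kk[c0 + 1] != 0.0:
            acc -= kk[c0 + 1] * (pos - dval[c0 + 1])
        out[2 * node] = vel
        out[2 * node + 1] = acc


@njit(cache=True)
def ring_loop(x0, n, h, a, w1, w2, d, e, rho, om, kk, off, tau, src, mode):
    """mode 0: nearest-sample delayed lookup; mode 1: linear interpolation."""
    dim = 6
    hist = np.empty((n + 1, dim))
    hist[0] = x0
    s = x0.copy()
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    tmp = np.empty(dim)
    dval = np.empty(6)
    for i in range(n):
        t = i * h
        for c in range(6):
            if mode == 0:
                j = i - off[c]
                if j < 0:
                    j = 0
                dval[c] = hist[j, src[c]]
            else:
                tq = t - tau[c]
                if tq <= 0.0:
                    dval[c] = hist[0, src[c]]
                else:
                    jf = tq / h
                    j = int(math.floor(jf))
                    if j >= i:
                        dval[c] = hist[i, src[c]]
                    else:
                        frac = jf - j
                        dval[c] = ((1.0 - frac) * hist[j, src[c]]
                                   + frac * hist[j + 1, src[c]])
        _ring_deriv(s, t, a, w1, w2, d, e, rho, om, kk, dval, k1)
        for m in range(dim):
            tmp[m] = s[m] + 0.5 * h * k1[m]
        _ring_deriv(tmp, t + 0.5 * h, a, w1, w2, d, e, rho, om, kk, dval, k2)
        for m in range(dim):
            tmp[m] = s[m] + 0.5 * h * k2[m]
        _ring_deriv(tmp, t + 0.5 * h, a, w1, w2, d, e, rho, om, kk, dval, k3)
        for m in range(dim):
            tmp[m] = s[m] + h * k3[m]
        _ring_deriv(tmp, t + h, a, w1, w2, d, e, rho, om, kk, dval, k4)
        ok = True
        for m in range(dim):
            s[m] = s[m] + (h / 6.0) * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
            if not np.isfinite(s[m]):
                ok = False
        hist[i + 1] = s
        if not ok:
            return hist, i + 1
    return hist, n + 1


@njit(cache=True)
def _qp_deriv(s, t, omega, ka, kb, kth, A, fr, out):
    x = s[0]
    y = s[1]
    alpha = 1.0 - math.sqrt(x * x + y * y)
    out[0] = alpha * x - omega * y
    out[1] = alpha * y + omega * x
    theta = math.atan2(y, x)
    z0 = A * math.sin(2.0 * math.pi * fr * t)
    sP = 0.0
    sC = 0.0
    sT = 0.0
    for kdx in range(7):
        dth = theta - kth[kdx]
        dth = (dth + math.pi) % (2.0 * math.pi) - math.pi
        g = ka[kdx] * dth * math.exp(-dth * dth / (2.0 * kb[kdx] * kb[kdx]))
        if kdx < 2:
            sP += g
        elif kdx < 5:
            sC += g
        else:
            sT += g
    out[2] = -sP - (s[2] - z0)
    out[3] = -sC - (s[3] - z0)
    out[4] = -sT - (s[4] - z0)


@njit(cache=True)
def qp_loop(x0, n, h, ka, kb, kth, omega_arr, A, fr):
    """``omega_arr[i]`` is the angular frequency used throughout step i."""
    dim = 5
    hist = np.empty((n + 1, dim))
    hist[0] = x0
    s = x0.copy()
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    tmp = np.empty(dim)
    for i in range(n):
        t = i * h
        omega = omega_arr[i]
        _qp_deriv(s, t, omega, ka, kb, kth, A, fr, k1)
        for m in range(dim):
            tmp[m] = s[m] + 0.5 * h * k1[m]
        _qp_deriv(tmp, t + 0.5 * h, omega, ka, kb, kth, A, fr, k2)
        for m in range(dim):
            tmp[m] = s[m] + 0.5 * h * k2[m]
        _qp_deriv(tmp, t + 0.5 * h, omega, ka, kb, kth, A, fr, k3)
        for m in range(dim):
            tmp[m] = s[m] + h * k3[m]
        _qp_deriv(tmp, t + h, omega, ka, kb, kth, A, fr, k4)
        ok = True
        for m in range(dim):
            s[m] = s[m] + (h / 6.0) * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
            if not np.isfinite(s[m]):
                ok = False
        hist[i + 1] = s
        if not ok:
            return hist, i + 1
    return hist, n + 1
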