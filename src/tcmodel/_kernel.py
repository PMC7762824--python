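"""Compiled inner loop of the delayed-Euler integrator.

The numerical content mirrors :meth:`PhysicalModel.derivative` exactly; the
kernel exists because every model fit costs thousands of full integrations.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _derivative(y, dy, f, drive_a, drive_n, drive_g,
                GA, GN, GG, ratio, kappa, Vrev, C, sqrt_disp, threshold,
                mg_alpha, u, g_leak, V_leak, m_gain, h_gain,
                m_half, m_slope, h_half, h_slope, has_mh, spp, n):
    # kappa/Vrev order: AMPA, NMDA, GABA_A, GABA_B, M, H
    for i in range(n):
        v = y[i * spp]
        f[i] = 0.5 * (1.0 + math.erf((v - threshold) / (SQRT2 * sqrt_disp[i])))
    for i in range(n):
        sa = 0.0
        sn = 0.0
        sg = 0.0
        for j in range(n):
            sa += GA[i, j] * f[j]
            sn += GN[i, j] * f[j]
            sg += GG[i, j] * f[j]
        drive_a[i] = sa
        drive_n[i] = sn
        drive_g[i] = sg
    for i in range(n):
        base = i * spp
        v = y[base]
        gA = y[base + 1]
        gGa = y[base + 2]
        gN = y[base + 3]
        gGb = y[base + 4]
        mg = 1.0 / (1.0 + 0.2 * math.exp(-mg_alpha * v))
        current = (g_leak * (V_leak - v)
                   + gA * (Vrev[0] - v)
                   + gGa * (Vrev[2] - v)
                   + mg * gN * (Vrev[1] - v)
                   + gGb * (Vrev[3] - v))
        dy[base + 1] = kappa[0] * (drive_a[i] - gA)
        dy[base + 2] = kappa[2] * (drive_g[i] - gGa)
        dy[base + 3] = kappa[1] * (drive_n[i] - gN)
        dy[base + 4] = kappa[3] * (ratio * drive_g[i] - gGb)
        if has_mh:
            gM = y[base + 5]
            gH = y[base + 6]
            m_inf = m_gain[i] / (1.0 + math.exp(-(v - m_half) / m_slope))
            h_inf = h_gain[i] / (1.0 + math.exp((v - h_half) / h_slope))
            dy[base + 5] = kappa[4] * (m_inf - gM)
            dy[base + 6] = kappa[5] * (h_inf - gH)
            current += gM * (Vrev[4] - v) + gH * (Vrev[5] - v)
        current += u[i]
        dy[base] = current / C[i]


@njit(cache=True)
def integrate_loop(y0, n_steps, n_keep, dt_ms, Q, use_q,
                   GA, GN, GG, ratio, kappa, Vrev, C, sqrt_disp, threshold,
                   mg_alpha, u, g_leak, V_leak, m_gain, h_gain,
                   m_half, m_slope, h_half, h_slope, has_mh, spp, n,
                   guard, out):
    """Delayed-Euler loop; returns the 1-based step of divergence, or 0."""
    ns = y0.size
    y = y0.copy()
    dy = np.empty(ns)
    qdy = np.empty(ns)
    f = np.empty(n)
    da = np.empty(n)
    dn = np.empty(n)
    dg = np.empty(n)
    k = 0
    for step in range(n_steps):
        _derivative(y, dy, f, da, dn, dg, GA, GN, GG, ratio, kappa, Vrev, C,
                    sqrt_disp, threshold, mg_alpha, u, g_leak, V_leak,
                    m_gain, h_gain, m_half, m_slope, h_half, h_slope,
                    has_mh, spp, n)
        if use_q:
            for a in range(ns):
                acc = 0.0
                for b in range(ns):
                    acc += Q[a, b] * dy[b]
                qdy[a] = acc
            for a in range(ns):
                y[a] = y[a] + dt_ms * qdy[a]
        else:
            for a in range(ns):
                y[a] = y[a] + dt_ms * dy[a]
        for i in range(n):
            v = y[i * spp]
            if not math.isfinite(v) or abs(v) > guard:
                return step + 1
        if step >= n_steps - n_keep:
            out[:, k] = y
            k += 1
    return 0
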