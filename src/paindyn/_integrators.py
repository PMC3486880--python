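"""Compiled integration kernels.

Fixed-step classical RK4 for the second-order perception model (with the
reflecting non-negativity clamp applied after every substep) and the exact
exponential-integrator update for the leaky first-order family.  Batch
variants accumulate the residual sum of squares directly so a 20,000-draw
random search never materializes 20,000 trajectories.

The stimulus enters pre-sampled on a fine substep grid (temperature and its
central-difference derivative); measured and generated stimuli are treated
identically.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def rk4_second_traj(k1, gamma, k2, T0, Tc, Tf, dTf, n_sub, h, P0, dP0):
    """Second-order model trajectory sampled on the coarse grid.

    d²P/dt² = k1·max(0, T−T0) − gamma·dP/dt + k2·(dT/dt − Tc)·P,
    clamped so that P ≥ 0 (reflecting: P←0, dP←max(dP, 0)).
    """
    nf = Tf.shape[0]
    n = (nf - 1) // n_sub + 1
    out = np.empty(n)
    P = P0
    dP = dP0
    if P < 0.0:
        P = 0.0
    out[0] = P
    for i in range(nf - 1):
        Ta = Tf[i]
        Tb = Tf[i + 1]
        Tm = 0.5 * (Ta + Tb)
        da = dTf[i]
        db = dTf[i + 1]
        dm = 0.5 * (da + db)
        ua = Ta - T0 if Ta > T0 else 0.0
        um = Tm - T0 if Tm > T0 else 0.0
        ub = Tb - T0 if Tb > T0 else 0.0
        a1 = dP
        b1 = k1 * ua - gamma * dP + k2 * (da - Tc) * P
        a2 = dP + 0.5 * h * b1
        b2 = k1 * um - gamma * a2 + k2 * (dm - Tc) * (P + 0.5 * h * a1)
        a3 = dP + 0.5 * h * b2
        b3 = k1 * um - gamma * a3 + k2 * (dm - Tc) * (P + 0.5 * h * a2)
        a4 = dP + h * b3
        b4 = k1 * ub - gamma * a4 + k2 * (db - Tc) * (P + h * a3)
        P = P + h / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        dP = dP + h / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        if P < 0.0:
            P = 0.0
            if dP < 0.0:
                dP = 0.0
        if (i + 1) % n_sub == 0:
            out[(i + 1) // n_sub] = P
    return out


@njit(cache=False)
def rk4_second_sse_batch(theta, Tf, dTf, n_sub, h, obs):
    """SSE of the second-order model vs observed ratings, per parameter row.

    theta columns: k1, gamma, k2, T0, Tc.  Zero initial state.
    """
    m = theta.shape[0]
    nf = Tf.shape[0]
    sse = np.empty(m)
    for j in range(m):
        k1 = theta[j, 0]
        gamma = theta[j, 1]
        k2 = theta[j, 2]
        T0 = theta[j, 3]
        Tc = theta[j, 4]
        P = 0.0
        dP = 0.0
        acc = (P - obs[0]) ** 2
        for i in range(nf - 1):
            Ta = Tf[i]
            Tb = Tf[i + 1]
            Tm = 0.5 * (Ta + Tb)
            da = dTf[i]
            db = dTf[i + 1]
            dm = 0.5 * (da + db)
            ua = Ta - T0 if Ta > T0 else 0.0
            um = Tm - T0 if Tm > T0 else 0.0
            ub = Tb - T0 if Tb > T0 else 0.0
            a1 = dP
            b1 = k1 * ua - gamma * dP + k2 * (da - Tc) * P
            a2 = dP + 0.5 * h * b1
            b2 = k1 * um - gamma * a2 + k2 * (dm - Tc) * (P + 0.5 * h * a1)
            a3 = dP + 0.5 * h * b2
            b3 = k1 * um - gamma * a3 + k2 * (dm - Tc) * (P + 0.5 * h * a2)
            a4 = dP + h * b3
            b4 = k1 * ub - gamma * a4 + k2 * (db - Tc) * (P + h * a3)
            P = P + h / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            dP = dP + h / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            if P < 0.0:
                P = 0.0
                if dP < 0.0:
                    dP = 0.0
            if (i + 1) % n_sub == 0:
                d = P - obs[(i + 1) // n_sub]
                acc += d * d
        sse[j] = acc
    return sse


@njit(cache=False)
def leaky_traj(A, tau, T0, delta, Tmid, dt, P0):
    """Exact exponential-integrator trajectory of dP/dt = A·u − P/tau.

    u = max(0, T−T0)^delta with the drive defined as 0 at exactly T = T0
    (limit from below threshold), avoiding 0^negative.  ``Tmid`` holds the
    step-midpoint temperatures; exact when the drive is constant per step.
    """
    n = Tmid.shape[0] + 1
    out = np.empty(n)
    e = np.exp(-dt / tau)
    c = A * tau * (1.0 - e)
    P = P0
    out[0] = P
    for i in range(n - 1):
        x = Tmid[i] - T0
        if x > 0.0:
            u = x if delta == 1.0 else x ** delta
        else:
            u = 0.0
        P = P * e + c * u
        out[i + 1] = P
    return out


@njit(cache=False)
def leaky_sse_batch(theta, Tmid, dt, obs):
    """SSE of the leaky family per parameter row (columns: A, tau, T0, delta)."""
    m = theta.shape[0]
    n = Tmid.shape[0] + 1
    sse = np.empty(m)
    for j in range(m):
        A = theta[j, 0]
        tau = theta[j, 1]
        T0 = theta[j, 2]
        delta = theta[j, 3]
        e = np.exp(-dt / tau)
        c = A * tau * (1.0 - e)
        P = 0.0
        acc = (P - obs[0]) ** 2
        for i in range(n - 1):
            x = Tmid[i] - T0
            if x > 0.0:
                u = x if delta == 1.0 else x ** delta
            else:
                u = 0.0
            P = P * e + c * u
            d = P - obs[i + 1]
            acc += d * d
        sse[j] = acc
    return sse


@njit(cache=False)
def twotau_sse_batch(theta, Tmid, dt, obs):
    """SSE of the two-time-constant model per parameter row.

    theta columns: A_fast, tau_fast, A_slow, tau_slow, T0.  Two independent
    leaky processes share the threshold; output is their sum.
    """
    m = theta.shape[0]
    n = Tmid.shape[0] + 1
    sse = np.empty(m)
    for j in range(m):
        Af = theta[j, 0]
        tf = theta[j, 1]
        As = theta[j, 2]
        ts = theta[j, 3]
        T0 = theta[j, 4]
        ef = np.exp(-dt / tf)
        cf = Af * tf * (1.0 - ef)
        es = np.exp(-dt / ts)
        cs = As * ts * (1.0 - es)
        Pf = 0.0
        Ps = 0.0
        acc = obs[0] ** 2
        for i in range(n - 1):
            x = Tmid[i] - T0
            u = x if x > 0.0 else 0.0
            Pf = Pf * ef + cf * u
            Ps = Ps * es + cs * u
            d = Pf + Ps - obs[i + 1]
            acc += d * d
        sse[j] = acc
    return sse
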