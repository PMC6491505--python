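"""Batched fixed-step RK4 integrator for the neural + balloon state equations.

The batch axis carries independent parameter sets (finite-difference
perturbations during model inversion, or subjects), all driven by the same
input streams.  Compiled with numba; the first call in a process pays the
JIT cost.

State layout per batch element and region: (x, s, f, v, q) — neural state,
vasodilatory signal, blood flow, venous volume, deoxyhemoglobin.  Inputs are
held constant across each RK4 step (they are boxcars on the same grid).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_batch"]


@njit(fastmath=False)
def _deriv(y, ut, A, B, C, D, kappa, gamma, tau, alpha, e0, dy):
    P, n, _ = y.shape
    m = ut.shape[0]
    inv_alpha = 1.0 / alpha
    one_m_e0 = 1.0 - e0
    for p in range(P):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                aij = A[p, i, j]
                for r in range(m):
                    aij += ut[r] * B[p, r, i, j]
                for k in range(n):
                    aij += y[p, k, 0] * D[p, k, i, j]
                acc += aij * y[p, j, 0]
            for r in range(m):
                acc += C[p, i, r] * ut[r]
            dy[p, i, 0] = acc
        for i in range(n):
            x_ = y[p, i, 0]
            s_ = y[p, i, 1]
            f_ = y[p, i, 2]
            v_ = y[p, i, 3]
            q_ = y[p, i, 4]
            dy[p, i, 1] = x_ - kappa * s_ - gamma * (f_ - 1.0)
            dy[p, i, 2] = s_
            fv = v_ ** inv_alpha
            dy[p, i, 3] = (f_ - fv) / tau[p]
            dy[p, i, 4] = (f_ * (1.0 - one_m_e0 ** (1.0 / f_)) / e0
                           - fv * q_ / v_) / tau[p]


@njit(fastmath=False)
def integrate_batch(A, B, C, D, u, dt, sample_idx, kappa, gamma, tau,
                    alpha, e0, v0, x_bound):
    """Integrate a batch of DCMs and sample BOLD at given step indices.

    Parameters
    ----------
    A : (P, n, n) effective intrinsic matrices (negative self-connections
        already on the diagonal).
    B : (P, m, n, n) input-modulatory matrices, one per input stream.
    C : (P, n, m) driving-input weights.
    D : (P, n, n, n) gating matrices; D[p, k] is the matrix gated by the
        activity of region k.
    u : (T, m) input streams on the dt grid.
    sample_idx : int64 array of step indices at which BOLD is recorded.
    tau : (P,) transit times (the one free hemodynamic parameter).
    x_bound : neural-state magnitude above which integration is declared
        divergent for that batch element.

    Returns
    -------
    bold : (P, len(sample_idx), n) sampled BOLD.
    fail_step : (P,) first step at which the element failed, or -1.
    """
    P, n, _ = A.shape
    T = u.shape[0]
    S = sample_idx.shape[0]
    bold = np.zeros((P, S, n))
    fail = np.full(P, -1, dtype=np.int64)
    y = np.zeros((P, n, 5))
    for p in range(P):
        for i in range(n):
            y[p, i, 2] = 1.0
            y[p, i, 3] = 1.0
            y[p, i, 4] = 1.0
    k1 = np.zeros((P, n, 5))
    k2 = np.zeros((P, n, 5))
    k3 = np.zeros((P, n, 5))
    k4 = np.zeros((P, n, 5))
    ytmp = np.zeros((P, n, 5))
    k1c = 7.0 * e0
    k2c = 2.0
    k3c = 2.0 * e0 - 0.2
    isample = 0
    for t in range(T):
        if isample < S and t == sample_idx[isample]:
            for p in range(P):
                for i in range(n):
                    v_ = y[p, i, 3]
                    q_ = y[p, i, 4]
                    bold[p, isample, i] = v0 * (k1c * (1.0 - q_)
                                                + k2c * (1.0 - q_ / v_)
                                                + k3c * (1.0 - v_))
            isample += 1
        ut = u[t]
        _deriv(y, ut, A, B, C, D, kappa, gamma, tau, alpha, e0, k1)
        for p in range(P):
            for i in range(n):
                for c in range(5):
                    ytmp[p, i, c] = y[p, i, c] + 0.5 * dt * k1[p, i, c]
        _deriv(ytmp, ut, A, B, C, D, kappa, gamma, tau, alpha, e0, k2)
        for p in range(P):
            for i in range(n):
                for c in range(5):
                    ytmp[p, i, c] = y[p, i, c] + 0.5 * dt * k2[p, i, c]
        _deriv(ytmp, ut, A, B, C, D, kappa, gamma, tau, alpha, e0, k3)
        for p in range(P):
            for i in range(n):
                for c in range(5):
                    ytmp[p, i, c] = y[p, i, c] + dt * k3[p, i, c]
        _deriv(ytmp, ut, A, B, C, D, kappa, gamma, tau, alpha, e0, k4)
        for p in range(P):
            if fail[p] >= 0:
                continue
            bad = False
            for i in range(n):
                for c in range(5):
                    y[p, i, c] += (dt / 6.0) * (k1[p, i, c]
                                                + 2.0 * k2[p, i, c]
                                                + 2.0 * k3[p, i, c]
                                                + k4[p, i, c])
                xv = y[p, i, 0]
                if not np.isfinite(xv) or xv > x_bound or xv < -x_bound:
                    bad = True
                if y[p, i, 3] <= 0.0 or y[p, i, 4] <= 0.0:
                    bad = True
            if bad:
                fail[p] = t
                for i in range(n):  # freeze at rest so bold stays defined
                    y[p, i, 0] = 0.0
                    y[p, i, 1] = 0.0
                    y[p, i, 2] = 1.0
                    y[p, i, 3] = 1.0
                    y[p, i, 4] = 1.0
    while isample < S:
        # sample indices beyond the input grid: hold the final state
        for p in range(P):
            for i in range(n):
                v_ = y[p, i, 3]
                q_ = y[p, i, 4]
                bold[p, isample, i] = v0 * (k1c * (1.0 - q_)
                                            + k2c * (1.0 - q_ / v_)
                                            + k3c * (1.0 - v_))
        isample += 1
    return bold, fail
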