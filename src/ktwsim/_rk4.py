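"""Numba inner loop: classical RK4 integration to the first extinction.

Step size adapts to the fastest per-capita rate so that stiff transients
(e.g. a phage blooming on an abundant host, beta*eta up to 50) stay accurate
while the long exponential decay toward the 1e-20 extinction threshold runs
at the cap h_max. Steps producing NaNs or densities below -1e-12 are retried
with a halved step.
"""

import numpy as np
from numba import njit

# status codes returned by rk4_until_extinction
EXTINCT = 0
NO_EXTINCTION = 1
NUMERICAL_FAILURE = 2


@njit(cache=True)
def glv_rates(k, alpha, eta, beta, delta, B, P):
    N = B.shape[0]
    M = P.shape[0]
    tot = 0.0
    for i in range(N):
        tot += B[i]
    dB = np.empty(N)
    dP = np.empty(M)
    for i in range(N):
        s = 0.0
        for q in range(M):
            s += eta[q, i] * P[q]
        dB[i] = B[i] * (k[i] * (1.0 - tot) - alpha - s)
    for q in range(M):
        s = 0.0
        for i in range(N):
            s += eta[q, i] * B[i]
        dP[q] = P[q] * (beta[q] * s - delta)
    return dB, dP


@njit(cache=True)
def rk4_until_extinction(k, alpha, eta, beta, delta, B0, P0,
                         threshold, h_max, t_max):
    """Integrate until any density drops below `threshold`.

    Returns (status, kind, index, t, B, P) where kind is 0 for a bacterium,
    1 for a phage; on simultaneous crossings the strain with the smallest
    density is reported.
    """
    N = B0.shape[0]
    M = P0.shape[0]
    B = B0.copy()
    P = P0.copy()
    t = 0.0
    h_cap = h_max
    streak = 0
    while t < t_max:
        dB1, dP1 = glv_rates(k, alpha, eta, beta, delta, B, P)
        # Density gates for tail extrapolation: a strain below its gate has
        # negligible influence on the rest of the community, so once it is
        # clearly decaying in a quasi-static environment its remaining path
        # to `threshold` is exponential. A bacterium feeds phages at up to
        # beta*eta*B ~ 50 B per capita (gate 1e-4; 0.05 with no phages,
        # where only its resource share sum_j B_j matters); a phage only
        # presses bacteria at eta*P < P (gate 1e-3).
        b_gate = 0.05 if M == 0 else 1e-4
        p_gate = 1e-3
        b_coup = 1.0 if M == 0 else 50.0  # max per-capita influence per unit density
        gmax = 0.0
        n_active = 0
        min_g = 1e300  # slowest active per-capita rate (magnitude)
        env_g = 0.0  # fastest non-active per-capita rate
        coup = 0.0  # bound on the active strains' influence on anything
        for i in range(N):
            if B[i] > 0.0:
                g = dB1[i] / B[i]
                ag = abs(g)
                if ag > gmax:
                    gmax = ag
                if B[i] < b_gate and ag > 1e-6:
                    n_active += 1
                    coup += b_coup * B[i]
                    if ag < min_g:
                        min_g = ag
                else:
                    if ag > env_g:
                        env_g = ag
        for q in range(M):
            if P[q] > 0.0:
                g = dP1[q] / P[q]
                ag = abs(g)
                if ag > gmax:
                    gmax = ag
                if P[q] < p_gate and ag > 1e-6:
                    n_active += 1
                    coup += P[q]
                    if ag < min_g:
                        min_g = ag
                else:
                    if ag > env_g:
                        env_g = ag
        # Asymptotic jump: strains below their influence gate are dynamically
        # negligible; if everything else is quasi-static relative to them,
        # each evolves exponentially at its frozen per-capita rate. Jump to
        # the first event — a decayer crossing `threshold` (extinction) or a
        # grower reaching its gate (where it starts to matter and normal
        # stepping resumes). The handed-off state feeds a fresh linear
        # steady-state solve, which corrects residual environment drift.
        if n_active > 0 and env_g < 0.02 * min_g and coup < 0.02 * min_g:
            t_jump = 1e300
            e_kind = -1
            e_idx = -1
            cross = False
            for i in range(N):
                if 0.0 < B[i] < b_gate:
                    g = dB1[i] / B[i]
                    if g < -1e-6:
                        te = np.log(B[i] / threshold) / (-g)
                        if te < t_jump:
                            t_jump = te
                            e_kind = 0
                            e_idx = i
                            cross = True
                    elif g > 1e-6:
                        te = np.log(1.01 * b_gate / B[i]) / g
                        if te < t_jump:
                            t_jump = te
                            e_kind = 0
                            e_idx = i
                            cross = False
            for q in range(M):
                if 0.0 < P[q] < p_gate:
                    g = dP1[q] / P[q]
                    if g < -1e-6:
                        te = np.log(P[q] / threshold) / (-g)
                        if te < t_jump:
                            t_jump = te
                            e_kind = 1
                            e_idx = q
                            cross = True
                    elif g > 1e-6:
                        te = np.log(1.01 * p_gate / P[q]) / g
                        if te < t_jump:
                            t_jump = te
                            e_kind = 1
                            e_idx = q
                            cross = False
            if e_kind >= 0 and t_jump < 1e300:
                for i in range(N):
                    if 0.0 < B[i] < b_gate:
                        g = dB1[i] / B[i]
                        if abs(g) > 1e-6:
                            B[i] = B[i] * np.exp(g * t_jump)
                for q in range(M):
                    if 0.0 < P[q] < p_gate:
                        g = dP1[q] / P[q]
                        if abs(g) > 1e-6:
                            P[q] = P[q] * np.exp(g * t_jump)
                t += t_jump
                if cross:
                    if e_kind == 0:
                        B[e_idx] = 0.0
                    else:
                        P[e_idx] = 0.0
                    return EXTINCT, e_kind, e_idx, t, B, P
                continue
        # Step size: accuracy-limited by the fastest per-capita rate
        # (gmax * h <= 0.25), stability-limited by the growing cap h_cap.
        # The cap expands while steps keep being accepted and collapses on a
        # rejection, so hidden stiff Jacobian modes (which blow up within a
        # few large steps and trip the NaN / negativity / log-jump guards)
        # throttle it automatically.
        h = h_cap
        if gmax * h > 0.25:
            h = 0.25 / gmax
        if h < h_max:
            h = min(h_max, h_cap)
        rejected = False
        accepted = False
        Bn = B
        Pn = P
        for _ in range(60):
            B2 = B + 0.5 * h * dB1
            P2 = P + 0.5 * h * dP1
            dB2, dP2 = glv_rates(k, alpha, eta, beta, delta, B2, P2)
            B3 = B + 0.5 * h * dB2
            P3 = P + 0.5 * h * dP2
            dB3, dP3 = glv_rates(k, alpha, eta, beta, delta, B3, P3)
            B4 = B + h * dB3
            P4 = P + h * dP3
            dB4, dP4 = glv_rates(k, alpha, eta, beta, delta, B4, P4)
            Bn = B + (h / 6.0) * (dB1 + 2.0 * dB2 + 2.0 * dB3 + dB4)
            Pn = P + (h / 6.0) * (dP1 + 2.0 * dP2 + 2.0 * dP3 + dP4)
            ok = True
            guard = h > 2.0 * h_max
            for i in range(N):
                if not np.isfinite(Bn[i]) or Bn[i] < -1e-12:
                    ok = False
                    break
                if guard and B[i] > 1e-18 and not \
                        0.49 * B[i] < Bn[i] < 2.01 * B[i]:
                    ok = False
                    break
            if ok:
                for q in range(M):
                    if not np.isfinite(Pn[q]) or Pn[q] < -1e-12:
                        ok = False
                        break
                    if guard and P[q] > 1e-18 and not \
                            0.49 * P[q] < Pn[q] < 2.01 * P[q]:
                        ok = False
                        break
            if ok:
                accepted = True
                break
            rejected = True
            h *= 0.5
        if rejected:
            h_cap = h * 2.0 if h * 2.0 > h_max else h_max
            streak = 0
        else:
            streak += 1
            if streak >= 32:
                streak = 0
                h_cap = h_cap * 1.5 if h_cap < 1e3 else h_cap
        if not accepted:
            return NUMERICAL_FAILURE, -1, -1, t, B, P
        for i in range(N):
            if Bn[i] < 0.0:
                Bn[i] = 0.0
        for q in range(M):
            if Pn[q] < 0.0:
                Pn[q] = 0.0
        B = Bn
        P = Pn
        t += h
        kind = -1
        idx = -1
        mn = threshold
        for i in range(N):
            if B[i] < mn:
                mn = B[i]
                kind = 0
                idx = i
        for q in range(M):
            if P[q] < mn:
                mn = P[q]
                kind = 1
                idx = q
        if kind >= 0:
            return EXTINCT, kind, idx, t, B, P
    return NO_EXTINCTION, -1, -1, t, B, P
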