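"""Numba kernels for the lattice Monte Carlo.

Strategies are encoded as ints (C=0, D=1, P=2, M=3).  Groups are the
five overlapping von Neumann groups each site belongs to: the group it
centres plus the four groups centred on its neighbours, G = 5 members
each.  The kernels share numba's global RNG state, so a run may be
executed in segments (for snapshots) without perturbing the stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _group_payoff(strat, n_C, n_D, n_P, n_M, G, r, c, alpha, beta, gamma, H):
    pi_C = r * (G - n_D) * c / G - c
    if strat == 0:  # C
        return pi_C
    if strat == 1:  # D
        trig = 1.0 if n_P - H >= 0 else 0.0
        return r * (G - n_D - 1) * c / G - (n_P + trig * n_M) * alpha
    if strat == 2:  # P
        trig = 1.0 if n_P + 1 - H >= 0 else 0.0
        return pi_C - n_D * beta / (n_P + trig * n_M + 1.0)
    # M
    trig = 1.0 if n_P - H >= 0 else 0.0
    return pi_C - trig * n_D * beta / (n_P + n_M + 1.0) - gamma


@njit(cache=True)
def _site_payoff(grid, L, i, j, G, r, c, alpha, beta, gamma, H):
    """Total payoff of site (i, j): sum over its five overlapping groups."""
    total = 0.0
    strat = grid[i, j]
    for g in range(5):
        if g == 0:
            ci, cj = i, j
        elif g == 1:
            ci, cj = (i + 1) % L, j
        elif g == 2:
            ci, cj = (i - 1) % L, j
        elif g == 3:
            ci, cj = i, (j + 1) % L
        else:
            ci, cj = i, (j - 1) % L
        n_C = 0
        n_D = 0
        n_P = 0
        n_M = 0
        for m in range(5):
            if m == 0:
                mi, mj = ci, cj
            elif m == 1:
                mi, mj = (ci + 1) % L, cj
            elif m == 2:
                mi, mj = (ci - 1) % L, cj
            elif m == 3:
                mi, mj = ci, (cj + 1) % L
            else:
                mi, mj = ci, (cj - 1) % L
            if mi == i and mj == j:
                continue
            sm = grid[mi, mj]
            if sm == 0:
                n_C += 1
            elif sm == 1:
                n_D += 1
            elif sm == 2:
                n_P += 1
            else:
                n_M += 1
        total += _group_payoff(strat, n_C, n_D, n_P, n_M, G, r, c, alpha, beta, gamma, H)
    return total


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _run_kernel(grid, L, G, r, c, alpha, beta, gamma, H, s, n_mcs):
    """Run n_mcs Monte Carlo steps; returns per-MCS strategy frequencies.

    One MCS = L*L elementary imitation attempts (random sequential with
    replacement).  Payoffs of the focal pair are recomputed from the
    current configuration at every attempt.  Row 0 of the output holds
    the initial frequencies.
    """
    counts = np.zeros(4, dtype=np.int64)
    for i in range(L):
        for j in range(L):
            counts[grid[i, j]] += 1
    freqs = np.empty((n_mcs + 1, 4))
    area = float(L * L)
    for k in range(4):
        freqs[0, k] = counts[k] / area
    for t in range(1, n_mcs + 1):
        for _ in range(L * L):
            u = np.random.randint(0, L * L)
            ui = u // L
            uj = u % L
            d = np.random.randint(0, 4)
            if d == 0:
                vi, vj = (ui + 1) % L, uj
            elif d == 1:
                vi, vj = (ui - 1) % L, uj
            elif d == 2:
                vi, vj = ui, (uj + 1) % L
            else:
                vi, vj = ui, (uj - 1) % L
            su = grid[ui, uj]
            sv = grid[vi, vj]
            if su == sv:
                continue
            pu = _site_payoff(grid, L, ui, uj, G, r, c, alpha, beta, gamma, H)
            pv = _site_payoff(grid, L, vi, vj, G, r, c, alpha, beta, gamma, H)
            x = s * (pv - pu)
            if x < -700.0:
                q = 0.0
            elif x > 700.0:
                q = 1.0
            else:
                q = 1.0 / (1.0 + np.exp(-x))
            if np.random.random() < q:
                grid[ui, uj] = sv
                counts[su] -= 1
                counts[sv] += 1
        for k in range(4):
            freqs[t, k] = counts[k] / area
    return freqs
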