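"""Replicator dynamics of the four-strategy game in an infinite well-mixed population.

The state is a point ``(x, y, z, w)`` on the simplex S4 giving the
frequencies of cooperators, defectors, unconditional punishers and
conditional punishers.  A strategy's expected payoff is the multinomial
average of its single-group payoff over all co-player compositions, and
each frequency grows at its payoff advantage over the population mean:

    dx/dt = x (P_C - Pbar),   and likewise for y, z, w.

Only two attractors exist for the parameter ranges of interest: the
all-defector vertex, and the neutrally stable defector-free segment
mixing cooperators with unconditional punishers (conditional punishers
die out there because of their observation cost).  The module provides
single-trajectory integration, endpoint classification, Monte Carlo
basin-of-attraction estimation on the simplex and its faces, and the
closed-form defector/punisher two-strategy analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .game import GameParams, Strategy, compositions, group_payoff, multinomial

__all__ = [
    "Outcome",
    "Trajectory",
    "BasinResult",
    "PayoffTable",
    "expected_payoffs",
    "average_payoff",
    "replicator_rhs",
    "integrate",
    "classify_endpoint",
    "basin_fraction",
    "face_basin_fraction",
    "dp_payoffs",
    "g_function",
    "find_interior_roots",
    "critical_fine",
]

_FACE_INDEX = {"C": 0, "D": 1, "P": 2, "M": 3}


class Outcome(Enum):
    DEFECTION = "defection"
    COOPERATIVE = "cooperative"
    UNRESOLVED = "unresolved"


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n_times, 4), rows on the simplex
    terminal_class: Outcome


@dataclass
class BasinResult:
    """Summary of a basin-of-attraction Monte Carlo estimate."""

    cooperative_fraction: float
    defection_fraction: float
    unresolved: int
    n_samples: int
    seed: int | None
    face: tuple[str, ...] = ("C", "D", "P", "M")

    @property
    def cooperative_percent(self) -> float:
        return 100.0 * self.cooperative_fraction


class PayoffTable:
    """Precomputed multinomial payoff expansion for fast expected payoffs.

    For each of the ``K`` co-player compositions ``(n_C, n_D, n_P, n_M)``
    of ``G - 1`` players, stores the exponent tuple and the product of
    the multinomial coefficient with the focal payoff, for all four
    focal strategies.  The expected payoff of strategy ``i`` at state
    ``(x, y, z, w)`` is then a 35-term (for G = 5) polynomial
    ``sum_k coef[k, i] * x**nC * y**nD * z**nP * w**nM``.
    """

    def __init__(self, params: GameParams):
        self.params = params
        comps = list(compositions(params.G))
        self.exponents = np.array([c.as_tuple() for c in comps], dtype=np.intp)
        coef = np.empty((len(comps), 4))
        for k, comp in enumerate(comps):
            m = multinomial(comp.as_tuple())
            for s in Strategy:
                coef[k, s] = m * group_payoff(s, comp, params)
        self.coefs = coef
        self._max_exp = params.G  # exponents run 0 .. G-1

    def payoffs(self, states: np.ndarray) -> np.ndarray:
        """Expected payoffs for a batch of states, shape (n, 4) -> (n, 4)."""
        S = np.atleast_2d(np.asarray(states, dtype=float))
        # per-variable power tables: pows[v][:, k] = S[:, v] ** k
        mono = np.ones((S.shape[0], self.exponents.shape[0]))
        for v in range(4):
            p = np.power.outer(S[:, v], np.arange(self._max_exp))
            mono *= p[:, self.exponents[:, v]]
        return mono @ self.coefs

    def rhs(self, states: np.ndarray) -> np.ndarray:
        S = np.atleast_2d(np.asarray(states, dtype=float))
        P = self.payoffs(S)
        pbar = np.sum(S * P, axis=1, keepdims=True)
        return S * (P - pbar)


@lru_cache(maxsize=64)
def _get_table(params: GameParams) -> PayoffTable:
    return PayoffTable(params)


def _as_state(state: Sequence[float]) -> np.ndarray:
    s = np.asarray(state, dtype=float)
    if s.shape != (4,):
        raise ValueError("state must have four components (x, y, z, w)")
    if np.any(s < -1e-9) or abs(s.sum() - 1.0) > 1e-9:
        raise ValueError(f"state must lie on the simplex, got {s}")
    return np.clip(s, 0.0, None)


def expected_payoffs(state: Sequence[float], params: GameParams) -> np.ndarray:
    """Expected payoff of each strategy at a mixed state (exhaustive multinomial sum)."""
    return _get_table(params).payoffs(_as_state(state))[0]


def average_payoff(state: Sequence[float], params: GameParams) -> float:
    s = _as_state(state)
    return float(s @ expected_payoffs(s, params))


def replicator_rhs(state: Sequence[float], params: GameParams) -> np.ndarray:
    """Time derivatives (xdot, ydot, zdot, wdot); they sum to zero."""
    return _get_table(params).rhs(_as_state(state))[0]


def classify_endpoint(
    state: Sequence[float],
    params: GameParams,
    eps: float = 1e-3,
    table: PayoffTable | None = None,
) -> Outcome:
    """Classify a (near-)converged state.

    DEFECTION when defectors have essentially taken over (``y > 1 - eps``);
    COOPERATIVE when both defectors and conditional punishers are
    essentially extinct *and* defectors cannot re-invade
    (``P_D < Pbar``, i.e. the state sits on the stable part of the
    cooperator/punisher segment); UNRESOLVED otherwise.
    """
    s = _as_state(state)
    if s[Strategy.D] > 1.0 - eps:
        return Outcome.DEFECTION
    if s[Strategy.D] < eps and s[Strategy.M] < eps:
        if table is None:
            table = PayoffTable(params)
        P = table.payoffs(s)[0]
        if P[Strategy.D] - float(s @ P) < 0.0:
            return Outcome.COOPERATIVE
    return Outcome.UNRESOLVED


def integrate(
    state0: Sequence[float],
    params: GameParams,
    t_max: float = 2000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    eps: float = 1e-3,
    extend_on_unresolved: bool = True,
) -> Trajectory:
    """Integrate one trajectory with an adaptive RK45 solver.

    The state is renormalized to the simplex after each segment; the
    integration horizon is doubled once if the endpoint is still
    unclassified at ``t_max``.
    """
    table = PayoffTable(params)

    def f(_t, y):
        return table.rhs(y)[0]

    s = _as_state(state0)
    times = [0.0]
    states = [s.copy()]
    t = 0.0
    horizon = t_max
    extended = False
    segment = max(t_max / 40.0, 1.0)
    outcome = classify_endpoint(s, params, eps, table)
    while outcome is Outcome.UNRESOLVED:
        sol = solve_ivp(f, (t, t + segment), s, method="RK45", rtol=rtol, atol=atol)
        s = np.clip(sol.y[:, -1], 0.0, None)
        s /= s.sum()
        t = sol.t[-1]
        times.append(t)
        states.append(s.copy())
        outcome = classify_endpoint(s, params, eps, table)
        if t >= horizon and outcome is Outcome.UNRESOLVED:
            if extend_on_unresolved and not extended:
                horizon *= 2.0
                extended = True
            else:
                break
    return Trajectory(np.array(times), np.array(states), outcome)


# ---------------------------------------------------------------------------
# Vectorized basin estimation
# ---------------------------------------------------------------------------


def _classify_batch(
    states: np.ndarray,
    params: GameParams,
    eps: float = 1e-3,
    dt: float = 0.05,
    t_max: float = 4000.0,
    check_interval: float = 20.0,
) -> np.ndarray:
    """Classify many initial conditions at once with a fixed-step RK4 stepper.

    Returns an integer array: 0 = cooperative, 1 = defection, 2 = unresolved.
    Trajectories are removed from the active set as soon as they classify,
    so the cost concentrates on the slow, near-separatrix ones.
    """
    table = PayoffTable(params)
    S = np.array(states, dtype=float)
    n = S.shape[0]
    out = np.full(n, 2, dtype=np.int8)
    active = np.arange(n)
    steps_per_check = max(int(round(check_interval / dt)), 1)
    n_checks = int(np.ceil(t_max / check_interval))

    for _ in range(n_checks):
        A = S[active]
        for _ in range(steps_per_check):
            k1 = table.rhs(A)
            k2 = table.rhs(np.clip(A + 0.5 * dt * k1, 0.0, None))
            k3 = table.rhs(np.clip(A + 0.5 * dt * k2, 0.0, None))
            k4 = table.rhs(np.clip(A + dt * k3, 0.0, None))
            A += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            np.clip(A, 0.0, None, out=A)
            A /= A.sum(axis=1, keepdims=True)
        S[active] = A
        P = table.payoffs(A)
        pbar = np.sum(A * P, axis=1)
        defect = A[:, Strategy.D] > 1.0 - eps
        coop = (
            (A[:, Strategy.D] < eps)
            & (A[:, Strategy.M] < eps)
            & (P[:, Strategy.D] - pbar < 0.0)
        )
        out[active[defect]] = 1
        out[active[coop]] = 0
        keep = ~(defect | coop)
        active = active[keep]
        if active.size == 0:
            break
    return out


def _sample_face(
    face: tuple[str, ...], n_samples: int, seed: int | None, sampler: str
) -> np.ndarray:
    idx = [_FACE_INDEX[f] for f in face]
    k = len(idx)
    if sampler == "uniform":
        rng = np.random.default_rng(seed)
        pts = rng.dirichlet(np.ones(k), size=n_samples)
    elif sampler == "grid":
        # deterministic barycentric grid with about n_samples interior points
        from itertools import combinations
        from math import comb

        m = 2
        while comb(m - 1, k - 1) < n_samples:
            m += 1
        pts_list = []
        for cuts in combinations(range(1, m), k - 1):
            prev = 0
            parts = []
            for cval in cuts:
                parts.append(cval - prev)
                prev = cval
            parts.append(m - prev)
            pts_list.append([p / m for p in parts])
        pts = np.array(pts_list)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    full = np.zeros((pts.shape[0], 4))
    full[:, idx] = pts
    return full


def basin_fraction(
    params: GameParams,
    n_samples: int = 10_000,
    seed: int | None = 0,
    sampler: str = "uniform",
    eps: float = 1e-3,
    t_max: float = 4000.0,
) -> BasinResult:
    """Fraction of the simplex S4 attracted to the cooperative segment.

    Initial conditions are drawn uniformly on the simplex (symmetric
    Dirichlet) or on a deterministic barycentric grid; each is integrated
    until it classifies as defection or cooperative coexistence.
    Unresolved trajectories are counted and reported, never dropped.
    """
    return face_basin_fraction(
        params, ("C", "D", "P", "M"), n_samples, seed, sampler, eps, t_max
    )


def face_basin_fraction(
    params: GameParams,
    face: tuple[str, ...],
    n_samples: int = 10_000,
    seed: int | None = 0,
    sampler: str = "uniform",
    eps: float = 1e-3,
    t_max: float = 4000.0,
) -> BasinResult:
    """Basin fraction restricted to a sub-simplex (face) of S4.

    Faces are invariant under the replicator dynamics, so sampling with
    the absent strategies at exactly zero stays on the face.
    """
    if not face or any(f not in _FACE_INDEX for f in face):
        raise ValueError(f"face must be a subset of C, D, P, M, got {face!r}")
    states = _sample_face(tuple(face), n_samples, seed, sampler)
    labels = _classify_batch(states, params, eps=eps, t_max=t_max)
    n = labels.size
    return BasinResult(
        cooperative_fraction=float(np.mean(labels == 0)),
        defection_fraction=float(np.mean(labels == 1)),
        unresolved=int(np.sum(labels == 2)),
        n_samples=n,
        seed=seed,
        face=tuple(face),
    )


# ---------------------------------------------------------------------------
# Defector / unconditional-punisher two-strategy analysis (closed forms)
# ---------------------------------------------------------------------------


def dp_payoffs(z, params: GameParams):
    """Closed-form expected payoffs ``(P_P, P_D)`` on the defector/punisher edge.

    ``z`` is the punisher frequency (defector frequency ``1 - z``).  The
    punisher expression has a removable singularity at ``z = 0``; the
    analytic limit ``rc/G - c + beta (1 - G)`` is used there.
    """
    G, r, c, alpha, beta = params.G, params.r, params.c, params.alpha, params.beta
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = np.where(z > 0, ((1.0 - z) ** G - 1.0) / np.where(z > 0, z, 1.0), -G)
    p_p = beta * bracket + (r * c / G) * ((G - 1) * z + 1.0) + beta - c
    p_d = (r * c / G - alpha) * (G - 1) * z
    return p_p, p_d


def g_function(z, params: GameParams):
    """Payoff advantage ``g(z) = P_P - P_D`` of punishers over defectors."""
    p_p, p_d = dp_payoffs(z, params)
    return p_p - p_d


def critical_fine(params: GameParams) -> float:
    """Fine above which the all-punisher edge state becomes stable: (G-r)c / (G(G-1))."""
    G, r, c = params.G, params.r, params.c
    return (G - r) * c / (G * (G - 1))


def find_interior_roots(
    params: GameParams, n_scan: int = 1000, tol: float = 1e-10
) -> list[float]:
    """Interior equilibria of the defector/punisher edge: roots of g in (0, 1).

    The exact ``g`` (not its linear approximation) is scanned on
    ``n_scan`` subintervals of ``(0, 1]`` for sign changes, each of which
    is refined by Brent bracketing.  An empty list means no interior
    equilibrium, which happens exactly when
    ``alpha <= (G - r) c / (G (G - 1))`` (then ``g(1) <= 0``).
    """
    zs = np.linspace(1e-9, 1.0, n_scan + 1)
    gs = np.asarray(g_function(zs, params))
    roots: list[float] = []
    for i in range(n_scan):
        a, b = gs[i], gs[i + 1]
        if a == 0.0:
            root = zs[i]
        elif a * b < 0.0:
            root = brentq(lambda z: float(g_function(z, params)), zs[i], zs[i + 1], xtol=tol)
        else:
            continue
        if 0.0 < root < 1.0 and not any(abs(root - r0) < 1e-8 for r0 in roots):
            roots.append(float(root))
    return roots
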