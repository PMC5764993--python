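"""Spatial public goods game on a periodic square lattice.

Players occupy the sites of an L x L lattice with periodic boundaries.
Each player belongs to five overlapping groups of size G = 5: the von
Neumann group it centres and the four groups centred on its neighbours.
A player's total payoff is the sum of its single-group payoffs over
those five groups.  Evolution is asynchronous imitation: per elementary
step a random site compares payoffs with a random neighbour and adopts
its strategy with Fermi probability; one Monte Carlo step (MCS) is
L^2 elementary steps, giving every site one update chance on average.

The heavy loops are compiled with numba (:mod:`condpunish._kernels`);
:func:`site_total_payoff` is an independent pure-Python evaluation used
to cross-check the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .game import GameParams, GroupComposition, Strategy, group_payoff
from .finite import fermi

__all__ = [
    "LatticeState",
    "LatticeRunResult",
    "init_lattice",
    "site_total_payoff",
    "mc_elementary_step",
    "run_mcs",
    "equilibrium_frequencies",
]

_VN = ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass
class LatticeState:
    """L x L grid of strategy codes with periodic boundary semantics."""

    grid: np.ndarray
    L: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.shape != (self.L, self.L):
            raise ValueError("grid shape must be (L, L)")
        if self.grid.min() < 0 or self.grid.max() > 3:
            raise ValueError("grid entries must be strategy codes 0..3")

    def frequencies(self) -> np.ndarray:
        return np.bincount(self.grid.ravel(), minlength=4) / self.L**2


@dataclass
class LatticeRunResult:
    """Frequency series (and optional snapshots) of one lattice run."""

    frequencies: np.ndarray  # shape (n_mcs + 1, 4); row t = state after t MCS
    seed: int
    params: GameParams
    s: float
    L: int
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)


def init_lattice(
    L: int,
    strategy_set: tuple[Strategy, ...] = (Strategy.C, Strategy.D, Strategy.P, Strategy.M),
    seed: int | None = 0,
) -> LatticeState:
    """Uniform i.i.d. initial configuration over the given strategy set."""
    if L < 4:
        raise ValueError("lattice side L must be >= 4")
    if not strategy_set:
        raise ValueError("strategy_set must be non-empty")
    rng = np.random.default_rng(seed)
    codes = np.array([int(s) for s in strategy_set], dtype=np.int8)
    return LatticeState(rng.choice(codes, size=(L, L)), L)


def site_total_payoff(state: LatticeState, site: tuple[int, int], params: GameParams) -> float:
    """Total payoff of one site: sum of group payoffs over its five groups.

    Pure-Python reference built directly on :func:`condpunish.game.group_payoff`;
    the compiled kernel is cross-checked against it.
    """
    if params.G != 5:
        raise ValueError("the von Neumann lattice requires G = 5")
    L = state.L
    i, j = site[0] % L, site[1] % L
    focal = Strategy(int(state.grid[i, j]))
    total = 0.0
    for di, dj in _VN:
        ci, cj = (i + di) % L, (j + dj) % L
        counts = [0, 0, 0, 0]
        for ei, ej in _VN:
            mi, mj = (ci + ei) % L, (cj + ej) % L
            if mi == i and mj == j:
                continue
            counts[int(state.grid[mi, mj])] += 1
        total += group_payoff(focal, GroupComposition(*counts), params)
    return total


def mc_elementary_step(
    state: LatticeState, params: GameParams, s: float, rng: np.random.Generator
) -> bool:
    """One asynchronous imitation attempt (pure-Python reference).

    Draws a random site and a random neighbour; if their strategies
    differ, the site adopts the neighbour's strategy with Fermi
    probability on their current total payoffs.  Returns True when a
    strategy change happened.
    """
    L = state.L
    u = int(rng.integers(L * L))
    ui, uj = divmod(u, L)
    di, dj = _VN[1 + int(rng.integers(4))]
    vi, vj = (ui + di) % L, (uj + dj) % L
    su, sv = int(state.grid[ui, uj]), int(state.grid[vi, vj])
    if su == sv:
        return False
    pu = site_total_payoff(state, (ui, uj), params)
    pv = site_total_payoff(state, (vi, vj), params)
    if rng.random() < float(fermi(pv - pu, s)):
        state.grid[ui, uj] = sv
        return True
    return False


def run_mcs(
    state: LatticeState,
    params: GameParams,
    s: float,
    n_mcs: int,
    seed: int = 0,
    snapshot_at: tuple[int, ...] = (),
) -> LatticeRunResult:
    """Evolve the lattice for ``n_mcs`` Monte Carlo steps (in place).

    The compiled kernel is seeded once and then advanced in segments
    between requested snapshot times, so the random stream — and hence
    the full frequency series — is independent of the snapshot schedule
    and bit-reproducible for a fixed seed.
    """
    if params.G != 5:
        raise ValueError("the von Neumann lattice requires G = 5")
    if n_mcs < 1:
        raise ValueError("n_mcs must be >= 1")
    snaps = sorted(set(int(t) for t in snapshot_at))
    if snaps and (snaps[0] < 0 or snaps[-1] > n_mcs):
        raise ValueError("snapshot times must lie in [0, n_mcs]")
    grid = state.grid
    _kernels._seed(seed)
    freqs = np.empty((n_mcs + 1, 4))
    snapshots: dict[int, np.ndarray] = {}
    if snaps and snaps[0] == 0:
        snapshots[0] = grid.copy()
        snaps = snaps[1:]
    t = 0
    first = True
    for t_next in snaps + [n_mcs]:
        if t_next > t:
            seg = _kernels._run_kernel(
                grid,
                state.L,
                params.G,
                params.r,
                params.c,
                params.alpha,
                params.beta,
                params.gamma,
                params.H,
                s,
                t_next - t,
            )
            if first:
                freqs[t : t_next + 1] = seg
                first = False
            else:
                freqs[t + 1 : t_next + 1] = seg[1:]
            t = t_next
        if t in (set(snapshot_at) - set(snapshots)):
            snapshots[t] = grid.copy()
    return LatticeRunResult(
        frequencies=freqs,
        seed=seed,
        params=params,
        s=s,
        L=state.L,
        snapshots=snapshots,
    )


def equilibrium_frequencies(
    results: list[LatticeRunResult],
    burn_in_fraction: float = 0.8,
    trend_tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, list[bool]]:
    """Time-and-run averaged strategy frequencies after burn-in.

    Each run is averaged over its final ``1 - burn_in_fraction`` window;
    a run is flagged non-converged when any strategy frequency still
    drifts with absolute linear trend above ``trend_tol`` per MCS over
    that window.  Returns ``(mean, run_to_run_sd, converged_flags)``;
    non-converged runs are flagged but *not* silently excluded from the
    average (callers decide).
    """
    if not results:
        raise ValueError("no runs supplied")
    if not (0.0 <= burn_in_fraction < 1.0):
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    per_run = []
    converged = []
    for res in results:
        f = res.frequencies
        start = int(burn_in_fraction * (f.shape[0] - 1))
        window = f[start:]
        per_run.append(window.mean(axis=0))
        tt = np.arange(window.shape[0])
        ok = True
        if window.shape[0] > 2:
            for k in range(4):
                slope = np.polyfit(tt, window[:, k], 1)[0]
                if abs(slope) > trend_tol:
                    ok = False
        converged.append(ok)
    arr = np.array(per_run)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(4)
    return arr.mean(axis=0), sd, converged
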