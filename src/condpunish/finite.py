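"""Stochastic evolutionary dynamics in a finite well-mixed population.

A population of constant size ``N`` holds ``X`` cooperators, ``Y``
defectors, ``Z`` unconditional punishers and ``W`` conditional
punishers.  Interaction groups of size ``G`` are sampled without
replacement, so a strategy's expected payoff is a multivariate
hypergeometric average of its single-group payoff over co-player
compositions.  Strategy updating follows the pairwise-comparison
(Fermi) rule with imitation strength ``s``; in the rare-exploration
limit the population hops between homogeneous states and its long-run
behaviour is captured by an embedded 4-state Markov chain whose
off-diagonal entries are fixation probabilities divided by three.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import multivariate_hypergeom

from .game import GameParams, Strategy, compositions, group_payoff

__all__ = [
    "PopulationCounts",
    "EvoParams",
    "finite_expected_payoffs",
    "fermi",
    "pairwise_transition",
    "fixation_probability",
    "embedded_markov_chain",
    "stationary_distribution",
    "strong_imitation_matrix",
    "simulate_wellmixed",
]


@dataclass(frozen=True)
class PopulationCounts:
    """Integer strategy counts (X, Y, Z, W) = (#C, #D, #P, #M)."""

    X: int
    Y: int
    Z: int
    W: int

    def __post_init__(self) -> None:
        for name in ("X", "Y", "Z", "W"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def N(self) -> int:
        return self.X + self.Y + self.Z + self.W

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z, self.W], dtype=np.int64)


@dataclass(frozen=True)
class EvoParams:
    """Update-rule parameters for the individual-based simulation."""

    s: float = 2.0  # imitation strength
    mu: float = 1e-3  # random exploration (mutation) rate per update
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("imitation strength s must be >= 0")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("exploration rate mu must lie in [0, 1]")


@lru_cache(maxsize=32)
def _comp_payoffs(params: GameParams) -> tuple[np.ndarray, np.ndarray]:
    """(comps, payoff matrix): payoff[k, i] of focal strategy i at composition k."""
    comps = list(compositions(params.G))
    carr = np.array([c.as_tuple() for c in comps], dtype=np.int64)
    pays = np.array(
        [[group_payoff(s, comp, params) for s in Strategy] for comp in comps]
    )
    return carr, pays


def finite_expected_payoffs(counts: PopulationCounts, params: GameParams) -> np.ndarray:
    """Expected payoff of each strategy present in the population.

    The focal player is excluded from its own sampling pool; co-player
    groups of size ``G - 1`` are drawn without replacement, giving
    multivariate hypergeometric composition weights.  Entries for absent
    strategies are NaN (their payoff is undefined).
    """
    m = counts.as_array()
    N = counts.N
    if N < params.G:
        raise ValueError(f"population size {N} smaller than group size {params.G}")
    comps, pays = _comp_payoffs(params)
    out = np.full(4, np.nan)
    for s in Strategy:
        if m[s] == 0:
            continue
        pool = m.copy()
        pool[s] -= 1
        w = multivariate_hypergeom.pmf(comps, m=pool, n=params.G - 1)
        out[s] = float(w @ pays[:, s])
    return out


def fermi(delta_p, s: float):
    """Pairwise-comparison adoption probability 1 / (1 + exp(-s * delta_p)).

    ``delta_p`` is the role model's payoff minus the focal's. Saturates
    cleanly to 0/1 for large |s * delta_p|.
    """
    if s < 0:
        raise ValueError("imitation strength s must be >= 0")
    return expit(s * np.asarray(delta_p, dtype=float))


def _two_strategy_payoffs(
    i: Strategy, j: Strategy, k_j: int, N: int, params: GameParams
) -> tuple[float, float]:
    """(P_i, P_j) when the population holds k_j players of j and N - k_j of i."""
    m = [0, 0, 0, 0]
    m[i] = N - k_j
    m[j] = k_j
    p = finite_expected_payoffs(PopulationCounts(*m), params)
    return float(p[i]), float(p[j])


def pairwise_transition(
    counts: PopulationCounts,
    i: Strategy,
    j: Strategy,
    params: GameParams,
    s: float,
) -> float:
    """Probability that the count of ``i`` drops by one in a single update.

    Valid for two-strategy states (only ``i`` and ``j`` present), as used
    in the fixation computation: a random focal ``i`` imitates a random
    ``j`` role model with Fermi probability.
    """
    m = counts.as_array()
    present = np.nonzero(m)[0]
    if not set(present).issubset({int(i), int(j)}):
        raise ValueError("pairwise_transition requires a two-strategy state")
    N = counts.N
    n_i = int(m[i])
    if n_i == 0 or n_i == N:
        return 0.0
    p = finite_expected_payoffs(counts, params)
    return n_i / N * (N - n_i) / N * float(fermi(p[j] - p[i], s))


def fixation_probability(
    resident: Strategy,
    mutant: Strategy,
    params: GameParams,
    N: int,
    s: float,
    method: str = "exp_sum",
) -> float:
    """Probability that a single mutant takes over a resident population.

    The one-dimensional birth--death chain over the mutant count has the
    standard absorption probability; two equivalent evaluations are
    provided.  ``exp_sum`` accumulates ``s * sum(P_res - P_mut)`` along
    the chain and combines the terms with log-sum-exp (robust for large
    ``s * N``); ``product`` multiplies the actual backward/forward
    transition-probability ratios in log space.  Neutral dynamics
    (``s = 0`` or equal payoffs) give exactly ``1/N``.
    """
    if N < 2:
        raise ValueError("population size N must be >= 2")
    if resident == mutant:
        raise ValueError("resident and mutant must differ")
    p_res = np.empty(N - 1)
    p_mut = np.empty(N - 1)
    for k in range(1, N):
        p_res[k - 1], p_mut[k - 1] = _two_strategy_payoffs(
            resident, mutant, k, N, params
        )
    if method == "exp_sum":
        exponents = np.concatenate(([0.0], np.cumsum(s * (p_res - p_mut))))
        if np.all(exponents == 0.0):  # neutral chain: exactly 1/N
            return 1.0 / N
        return float(np.exp(-logsumexp(exponents)))
    if method == "product":
        # log tau_{mut->res}(k) - log tau_{res->mut}(k); the count
        # prefactors cancel, leaving the ratio of the two Fermi draws
        log_ratios = np.empty(N - 1)
        for k in range(1, N):
            fwd = fermi(p_mut[k - 1] - p_res[k - 1], s)  # mutant count up
            bwd = fermi(p_res[k - 1] - p_mut[k - 1], s)  # mutant count down
            with np.errstate(divide="ignore"):
                log_ratios[k - 1] = np.log(bwd) - np.log(fwd)
        exponents = np.concatenate(([0.0], np.cumsum(log_ratios)))
        if np.all(exponents == 0.0):
            return 1.0 / N
        return float(np.exp(-logsumexp(exponents)))
    raise ValueError(f"unknown method {method!r}")


def stationary_distribution(P: np.ndarray) -> tuple[np.ndarray, bool]:
    """Stationary distribution of a row-stochastic matrix.

    Returns ``(pi, reducible)``.  For an irreducible chain ``pi`` is the
    normalized left eigenvector for eigenvalue 1; if the eigenspace is
    degenerate (reducible chain, e.g. the strong-imitation limit where
    the all-defector state is absorbing) the long-run distribution from
    a uniform start is returned and flagged.
    """
    P = np.asarray(P, dtype=float)
    from scipy.linalg import null_space

    ns = null_space(P.T - np.eye(P.shape[0]))
    if ns.shape[1] == 1:
        pi = ns[:, 0].real
        pi = np.abs(pi)
        return pi / pi.sum(), False
    # reducible: Cesaro limit from the uniform distribution
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    acc = np.zeros_like(pi)
    Pk = P.copy()
    for _ in range(200):
        Pk = Pk @ Pk  # P^(2^k): converges to the limiting projector
    pi = pi @ Pk
    return pi / pi.sum(), True


def embedded_markov_chain(
    params: GameParams, N: int, s: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Rare-exploration embedded chain over the four homogeneous states.

    Off-diagonal entries are ``rho_ij / 3`` (fixation probability of a
    single ``j`` mutant in an all-``i`` population, divided by the three
    available mutant strategies); diagonals absorb the remainder.
    Returns ``(transition_matrix, stationary, reducible_flag)``.
    """
    P = np.zeros((4, 4))
    for i in Strategy:
        for j in Strategy:
            if i == j:
                continue
            P[i, j] = fixation_probability(i, j, params, N, s) / 3.0
        P[i, i] = 1.0 - P[i].sum()
    pi, reducible = stationary_distribution(P)
    return P, pi, reducible


def strong_imitation_matrix(N: int) -> np.ndarray:
    """Analytic strong-imitation (s -> infinity) embedded transition matrix.

    In that limit each fixation probability is 0, 1 or the neutral 1/N:
    defectors always invade cooperative residents, punishers repel
    defectors, cooperators and unconditional punishers drift neutrally
    against each other, and conditional punishers lose to everyone
    (their observation cost, and their inability to punish without
    unconditional punishers present).
    """
    if N < 2:
        raise ValueError("population size N must be >= 2")
    return np.array(
        [
            [(2 * N - 1) / (3 * N), 1 / 3, 1 / (3 * N), 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [1 / (3 * N), 0.0, (3 * N - 1) / (3 * N), 0.0],
            [1 / 3, 1 / 3, 1 / 3, 0.0],
        ]
    )


def simulate_wellmixed(
    params: GameParams,
    evo: EvoParams,
    initial_counts: PopulationCounts,
    mutation_mode: str = "switch_other",
    record_every: int = 1,
) -> np.ndarray:
    """One stochastic mutation--selection path; returns counts per recorded step.

    Per update a focal player ``u`` is drawn uniformly.  With probability
    ``mu`` it mutates: in the default ``switch_other`` mode it adopts one
    of the *other* three strategies uniformly; ``uniform_all`` redraws
    from all four (an effective switch rate of 3 mu / 4).  Otherwise a
    random role model ``v != u`` is imitated with Fermi probability on
    the difference of expected payoffs at the current composition.

    The output array has shape ``(n_recorded, 4)``; row 0 is the initial
    state and a row is stored every ``record_every`` updates.
    """
    if mutation_mode not in ("switch_other", "uniform_all"):
        raise ValueError(f"unknown mutation_mode {mutation_mode!r}")
    rng = np.random.default_rng(evo.seed)
    m = initial_counts.as_array().copy()
    N = int(m.sum())
    if N < params.G:
        raise ValueError("population smaller than group size")

    cache: dict[tuple[int, int, int, int], np.ndarray] = {}

    def payoffs() -> np.ndarray:
        key = tuple(int(v) for v in m)
        p = cache.get(key)
        if p is None:
            p = finite_expected_payoffs(PopulationCounts(*key), params)
            cache[key] = p
        return p

    n_rec = evo.n_steps // record_every + 1
    out = np.empty((n_rec, 4), dtype=np.int64)
    out[0] = m
    rec = 1
    for step in range(1, evo.n_steps + 1):
        # strategy of the focal player, drawn proportionally to counts
        su = int(rng.choice(4, p=m / N))
        if rng.random() < evo.mu:
            if mutation_mode == "uniform_all":
                new = int(rng.integers(4))
            else:
                new = int(rng.integers(3))
                if new >= su:
                    new += 1
            if new != su:
                m[su] -= 1
                m[new] += 1
        else:
            # role model strategy among the other N - 1 players
            pool = m.copy()
            pool[su] -= 1
            sv = int(rng.choice(4, p=pool / (N - 1)))
            if sv != su:
                p = payoffs()
                if rng.random() < fermi(p[sv] - p[su], evo.s):
                    m[su] -= 1
                    m[sv] += 1
        if step % record_every == 0:
            out[rec] = m
            rec += 1
    return out[:rec]
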