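"""Single-group payoffs of the conditional-punishment public goods game.

Four strategies compete in groups of size ``G``:

* ``C`` — pure cooperator: contributes ``c`` to the common pool.
* ``D`` — pure defector: contributes nothing, may be fined.
* ``P`` — unconditional punisher: contributes and always fines each
  defector by ``alpha``, sharing the per-defector punishment cost
  ``beta`` with every active punisher.
* ``M`` — conditional punisher: contributes, pays a permanent
  observation cost ``gamma``, and joins the punishment activity only
  when the number of unconditional punishers in the group reaches the
  threshold ``H``.

All contributions are multiplied by the synergy factor ``r`` and split
equally among the ``G`` group members regardless of behaviour.  Payoffs
are expressed from the point of view of a *focal* player facing a
composition of ``G - 1`` co-players.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterator, Mapping

__all__ = [
    "Strategy",
    "GameParams",
    "GroupComposition",
    "heaviside",
    "group_payoff",
    "payoff_vector",
    "group_payoffs",
    "compositions",
]


class Strategy(IntEnum):
    """Stable integer encoding of the four strategies (used for array storage)."""

    C = 0
    D = 1
    P = 2
    M = 3


@dataclass(frozen=True)
class GameParams:
    """Static definition of one public goods game with conditional punishment.

    Parameters
    ----------
    G : int
        Group size, ``G >= 2``.
    r : float
        Synergy factor; the social dilemma requires ``1 < r < G``.
    c : float
        Contribution of every non-defector, in payoff units, ``c > 0``.
    alpha : float
        Fine imposed on each defector by each active punisher.
    beta : float
        Punishment cost per fined defector, shared equally among the
        punishers that take part in the sanction.
    gamma : float
        Permanent observation cost paid by conditional punishers.
    H : int
        Threshold number of unconditional punishers required to trigger
        conditional punishment; an integer with ``0 < H < G``.
    """

    G: int = 5
    r: float = 3.0
    c: float = 1.0
    alpha: float = 1.0
    beta: float = 0.7
    gamma: float = 0.05
    H: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.G, int) and self.G >= 2):
            raise ValueError(f"G must be an integer >= 2, got {self.G!r}")
        if not (1.0 < self.r < self.G):
            raise ValueError(f"synergy factor must satisfy 1 < r < G, got r={self.r}")
        if not self.c > 0:
            raise ValueError(f"contribution c must be positive, got {self.c}")
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not (isinstance(self.H, int) and 0 < self.H < self.G):
            raise ValueError(f"threshold must be an integer with 0 < H < G, got H={self.H!r}")


@dataclass(frozen=True)
class GroupComposition:
    """Counts of the ``G - 1`` co-players of a focal individual, by strategy."""

    n_C: int
    n_D: int
    n_P: int
    n_M: int

    def __post_init__(self) -> None:
        for name in ("n_C", "n_D", "n_P", "n_M"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_C + self.n_D + self.n_P + self.n_M

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_C, self.n_D, self.n_P, self.n_M)


def heaviside(u: int) -> int:
    """Discrete Heaviside step: 1 if ``u >= 0``, else 0."""
    return 1 if u >= 0 else 0


def _check_composition(comp: GroupComposition, params: GameParams) -> None:
    if comp.total != params.G - 1:
        raise ValueError(
            f"composition counts sum to {comp.total}, expected G - 1 = {params.G - 1}"
        )


def group_payoff(focal: Strategy, comp: GroupComposition, params: GameParams) -> float:
    """Payoff of a focal player of the given strategy in one group.

    ``comp`` counts the focal's co-players, so the focal itself is *not*
    included in the counts but is included in every share denominator.
    Note the deliberate asymmetry in the punishment trigger: a focal
    unconditional punisher counts itself toward the threshold
    (``H(n_P + 1 - H)``) whereas a focal conditional punisher does not
    (``H(n_P - H)``).
    """
    _check_composition(comp, params)
    G, r, c = params.G, params.r, params.c
    alpha, beta, gamma, H = params.alpha, params.beta, params.gamma, params.H
    n_C, n_D, n_P, n_M = comp.as_tuple()

    pi_C = r * (G - n_D) * c / G - c
    if focal is Strategy.C:
        return pi_C
    if focal is Strategy.D:
        return r * (G - n_D - 1) * c / G - (n_P + heaviside(n_P - H) * n_M) * alpha
    if focal is Strategy.P:
        share = n_P + heaviside(n_P + 1 - H) * n_M + 1
        return pi_C - n_D * beta / share
    if focal is Strategy.M:
        return pi_C - heaviside(n_P - H) * n_D * beta / (n_P + n_M + 1) - gamma
    raise ValueError(f"unknown strategy {focal!r}")


def payoff_vector(
    comp_by_focal: Mapping[Strategy, GroupComposition], params: GameParams
) -> tuple[float, float, float, float]:
    """Evaluate the four focal payoffs, one composition per focal strategy."""
    return tuple(group_payoff(s, comp_by_focal[s], params) for s in Strategy)  # type: ignore[return-value]


def group_payoffs(
    group_counts: tuple[int, int, int, int], params: GameParams
) -> dict[Strategy, float]:
    """Payoff of each strategy *present* in a full group of ``G`` members.

    ``group_counts`` are whole-group counts ``(N_C, N_D, N_P, N_M)``
    summing to ``G``; for each present strategy the focal is removed
    from its own count to form the co-player composition.
    """
    if sum(group_counts) != params.G:
        raise ValueError(f"group counts must sum to G = {params.G}")
    out: dict[Strategy, float] = {}
    for s in Strategy:
        if group_counts[s] == 0:
            continue
        counts = list(group_counts)
        counts[s] -= 1
        out[s] = group_payoff(s, GroupComposition(*counts), params)
    return out


def compositions(G: int) -> Iterator[GroupComposition]:
    """All co-player compositions of ``G - 1`` players over the four strategies."""
    n = G - 1
    for n_C in range(n + 1):
        for n_D in range(n - n_C + 1):
            for n_P in range(n - n_C - n_D + 1):
                yield GroupComposition(n_C, n_D, n_P, n - n_C - n_D - n_P)


def multinomial(counts: tuple[int, ...]) -> int:
    """Multinomial coefficient (sum(counts))! / prod(counts!)."""
    total = sum(counts)
    out = math.factorial(total)
    for k in counts:
        out //= math.factorial(k)
    return out
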