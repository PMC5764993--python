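# Methods

This note documents the models implemented in `condpunish`, the
numerical choices behind them, and what the test suite does and does not
establish.

## Game and parameters

A public goods game in groups of `G` players with four strategies
(cooperator C, defector D, unconditional punisher P, conditional
punisher M).  Defaults follow the benchmark parameterization used
throughout the tests: `G=5`, `c=1`, `r=3` (well-mixed analyses) or
`r=2` (lattice), fine `α=1.0`, shared sanction cost `β=0.7` (lattice:
`0.8`), observation cost `γ=0.05`, threshold `H∈{1,3}`.

| parameter | meaning | constraint |
|---|---|---|
| `G` | group size (players) | integer ≥ 2; lattice requires `G = 5` |
| `r` | synergy factor | `1 < r < G` (social dilemma) |
| `c` | contribution (payoff units) | `> 0` |
| `α` | fine per punisher per defector | `≥ 0` |
| `β` | sanction cost per fined defector, shared among active punishers | `≥ 0` |
| `γ` | observation cost of M per game | `≥ 0` |
| `H` | unconditional punishers needed to trigger M's punishment | integer, `0 < H < G` |
| `s` | imitation strength of the Fermi rule | `≥ 0`; default 2 |

Compositions are defined over *co-players* (the `G−1` others); the
focal player is added back in every sharing denominator, so payoffs are
finite for all valid compositions.  Two deliberate asymmetries of the
payoff definition are preserved exactly as specified: a focal P counts
itself toward the threshold (`δ(N_P + 1 − H)`), a focal M does not
(`δ(N_P − H)`); and the cost share of a focal M uses the denominator
`N_P + N_M + 1` (all conditional punishers in the group) even though its
trigger counts only unconditional punishers.  We do not harmonize the
two denominators.

## Infinite well-mixed populations

Expected payoffs are exact multinomial averages over all co-player
compositions (35 terms for `G=5`), precomputed once per parameter set as
a polynomial coefficient table; the replicator equations
`ẋᵢ = xᵢ(Pᵢ − P̄)` are integrated for all four frequencies and
renormalized (the fourth equation is implied by normalization; carrying
it explicitly is numerically more robust than eliminating it).

**Attractors and classification.**  For the parameter ranges studied
the flow ends either at the all-defector vertex or on the neutrally
stable defector-free C–P segment (M dies off there at rate `γ`).  An
endpoint is classified `DEFECTION` when `y > 1 − ε` and `COOPERATIVE`
when `y < ε`, `w < ε` *and* defectors cannot re-invade
(`P_D − P̄ < 0`, i.e. the state lies on the stable part of the
segment); anything else is `UNRESOLVED` and is counted, never dropped.
Default `ε = 10⁻³`.

**Basin estimation.**  Initial conditions are sampled uniformly on the
simplex (symmetric Dirichlet) by default; a deterministic barycentric
grid is available, and at matched resolution the two agree to ~0.1
percentage points.  Batches of trajectories are advanced together with
a fixed-step RK4 stepper (`dt = 0.05`, classification check every 20
time units, horizon `t = 4000`), removing trajectories from the active
set as they classify.  Single-trajectory `integrate` uses adaptive
RK45 (`rtol 10⁻⁸ / atol 10⁻¹⁰`) with one horizon doubling on an
unresolved endpoint; endpoint classes from the two integrators agree on
cross-checked initial conditions.

**D–P edge analysis.**  The closed-form edge payoffs have a removable
singularity at `z = 0`, replaced by the analytic limit
`rc/G − c + β(1 − G)`.  Interior equilibria are found by scanning the
*exact* payoff difference `g(z)` on 1000 subintervals of `(0, 1]` and
refining sign changes with Brent's method to `10⁻¹⁰` (the linear
approximation of `g` is used in the literature only to argue
monotonicity, so we do not rely on it; if `g` ever had several sign
changes, all roots would be returned).  The structure switches exactly
at the critical fine `α = (G − r)c/(G(G − 1))`: above it there is one
(unstable) interior root and both edge endpoints are stable; at or
below it there is none.

## Finite well-mixed populations

Expected payoffs enumerate co-player compositions with multivariate
hypergeometric weights (`scipy.stats.multivariate_hypergeom`), the
focal excluded from its own sampling pool.  This composition-sum
formulation is used instead of transcribing the printed nested-binomial
sums verbatim (one of which contains an index typo); it reproduces the
closed-form cooperator payoff to machine precision and Monte Carlo
group draws within sampling error.  Payoffs of absent strategies are
undefined and returned as NaN.  Population sizes below `G` are
rejected: a group of `G` players cannot be sampled from fewer.

Fixation probabilities of a single mutant are computed along the
two-strategy birth–death chain in two forms — the transition-ratio
product and the exponent-sum — which agree to `10⁻¹⁰`; both accumulate
in log space because `s · ΣΔP` can exceed 700 for `N = 100`.  Perfectly
neutral chains short-circuit to exactly `1/N`.  The rare-exploration
embedded Markov chain puts `ρ_ij/3` off the diagonal; its stationary
distribution is the eigenvalue-1 left null vector, or (flagged) the
long-run distribution from a uniform start when the chain is reducible,
as in the strong-imitation limit where the all-defector state is
absorbing.  The analytic strong-imitation matrix is provided as an
independent oracle; embedded chains built from real fixation
probabilities converge to it entrywise as `s` grows (max-entry error
`3×10⁻⁵` at `s = 200`, `N = 100`).

The individual-based simulation updates one random player per step:
with probability `μ` it switches to one of the *other three* strategies
uniformly (default, matching the `μ/3` convention; a redraw-from-all-four
variant is provided), otherwise it imitates a random other player under
the Fermi rule with payoffs recomputed for the current composition
(cached per composition, which is exact, not stale: the cache key is the
full count vector).

## Structured populations

Sites of an `L × L` periodic lattice hold one player each; every player
belongs to five overlapping von Neumann groups of size 5 (its own plus
the four centred on its neighbours) and its total payoff is the sum of
its single-group payoffs.  One Monte Carlo step (MCS) is `L²`
elementary updates, random sequential with replacement: a random site
and a random neighbour compare *current* total payoffs (recomputed on
demand, never cached across updates) and the site adopts the
neighbour's strategy with Fermi probability.  The inner loops are
numba-compiled; a pure-Python group-enumeration of the site payoff is
kept as an independent cross-check, and the punishment-free limit
(`α=β=γ=0`) matches a plain spatial PGG implementation exactly.  The
compiled RNG is seeded once per run, so snapshot scheduling does not
perturb the stream and fixed seeds give bit-identical frequency series.

**Equilibrium protocol.**  Runs last `2×10⁴` MCS by default; averages
use the final 20% of the series ("burn-in 80%"), with a per-strategy
linear-trend stationarity check (`10⁻⁴` per MCS) that flags — but does
not silently drop — non-converged runs.  These protocol constants are
package choices; ensembles default to 10 independent seeds at `L = 50`,
a scale at which equilibrium frequencies agree with `L = 100` within
run-to-run spread.

**Bistability at the benchmark lattice parameters.**  At `r=2.0`,
`α=1.0`, `β=0.8`, `s=2` the three-strategy control (no M) is bistable:
cooperators die first and every run is then absorbed into either all-D
or all-P.  The direction of a flat D|P interface can be computed by
hand from the summed group payoffs: the frontline defector earns
`2.8 − 7α = −4.2` while the frontline punisher earns
`2.2 − 4.75β = −1.6`, so punishers advance; simulations confirm
punishers win the majority of runs (≈6/10 at `L=50`, essentially all at
`L=100`).  Ensemble mean frequencies for these scenarios are therefore
averages of near-binary outcomes with run-to-run standard deviations
near 0.5, and they disagree with some previously reported equilibrium
values for this parameter set (punisher frequency ≈0.33 in the control,
≈0.15 at `H=3`); re-derivations under per-group-averaged payoffs,
temperature-style noise scaling and per-pair punishment accounting all
leave the punisher interface advantage intact, so the package reports
what the stated dynamics actually produces.  The qualitative
conclusions are robust and are what the acceptance properties assert:
with `H=1` the lattice reaches cooperator/punisher coexistence with
defectors and conditional punishers extinct, and the cooperative
ordering `H=1 > no-M control > H=3` holds on both replicator basins and
lattice equilibria.

## Synthetic data

All inputs are generated internally: Dirichlet/grid initial conditions
on the simplex, i.i.d. uniform lattice initializations over the active
strategy set, and seeded stochastic update sequences.  The generators
emulate the stated experimental conditions (equal initial frequencies,
`s = 2`, `μ = 10⁻³`, 10–30 independent runs) and nothing else: there is
no heterogeneity in thresholds, no alternative punishment regimes, no
other topologies.  A green test therefore establishes correctness of
the implemented dynamics under these stated conditions, not robustness
beyond them.

## Known limitations

* The separatrix between basins is only classified numerically, never
  characterized in closed form.
* The embedded Markov chain is the `μ → 0` limit; the full finite-`μ`
  four-strategy chain is simulated but not solved exactly.
* Basin percentages carry Monte Carlo error (~0.5 percentage points at
  10⁴ samples) plus a sampling-measure ambiguity of the same order.
* Lattice ensemble means at the benchmark parameters average near-binary
  absorbing outcomes (see above); comparisons against single reported
  equilibrium values at that parameter set should use win-fraction
  semantics and many seeds.
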