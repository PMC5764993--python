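"""Finite well-mixed population tests: hypergeometric payoffs, fixation, embedded chain."""

import numpy as np
import pytest

from condpunish import (
    EvoParams,
    GameParams,
    PopulationCounts,
    Strategy,
    embedded_markov_chain,
    expected_payoffs,
    fermi,
    finite_expected_payoffs,
    fixation_probability,
    pairwise_transition,
    simulate_wellmixed,
    stationary_distribution,
    strong_imitation_matrix,
)
from condpunish.game import GroupComposition, group_payoff


class TestFinitePayoffs:
    def test_closed_form_cooperator_payoff(self, fig1_params):
        """The enumeration reproduces the closed-form hypergeometric mean for cooperators."""
        p = fig1_params
        for counts in [
            PopulationCounts(25, 25, 25, 25),
            PopulationCounts(10, 60, 20, 10),
            PopulationCounts(1, 97, 1, 1),
        ]:
            N, Y = counts.N, counts.Y
            closed = p.r * p.c / p.G * ((p.G - 1) * (N - Y - 1) / (N - 1) + 1) - p.c
            got = finite_expected_payoffs(counts, p)[Strategy.C]
            assert got == pytest.approx(closed, abs=1e-13)

    def test_no_defectors_identities(self, fig1_params):
        pay = finite_expected_payoffs(PopulationCounts(40, 0, 30, 30), fig1_params)
        assert pay[Strategy.P] == pytest.approx(pay[Strategy.C], abs=1e-13)
        assert pay[Strategy.M] == pytest.approx(
            pay[Strategy.C] - fig1_params.gamma, abs=1e-13
        )

    def test_homogeneous_cooperators(self, fig1_params):
        pay = finite_expected_payoffs(PopulationCounts(100, 0, 0, 0), fig1_params)
        assert pay[Strategy.C] == pytest.approx(2.0)
        assert np.all(np.isnan(pay[1:]))  # absent strategies are undefined

    def test_monte_carlo_group_sampling_oracle(self, fig1_params, rng):
        """Exact expectations agree with brute-force random group draws within 3 SE."""
        p = fig1_params
        counts = PopulationCounts(25, 25, 25, 25)
        exact = finite_expected_payoffs(counts, p)
        n_draws = 200_000
        for s in Strategy:
            pool = counts.as_array().copy()
            pool[s] -= 1
            draws = rng.multivariate_hypergeometric(pool, p.G - 1, size=n_draws)
            vals = np.empty(n_draws)
            payoff_cache = {}
            for i, comp in enumerate(map(tuple, draws)):
                if comp not in payoff_cache:
                    payoff_cache[comp] = group_payoff(
                        s, GroupComposition(*map(int, comp)), p
                    )
                vals[i] = payoff_cache[comp]
            se = vals.std(ddof=1) / np.sqrt(n_draws)
            assert abs(vals.mean() - exact[s]) < 3 * se + 1e-9

    def test_converges_to_infinite_population_limit(self, fig1_params):
        """Hypergeometric payoffs approach the multinomial (replicator) payoffs as N grows."""
        inf_pay = expected_payoffs((0.25, 0.25, 0.25, 0.25), fig1_params)
        fin_pay = finite_expected_payoffs(PopulationCounts(1000, 1000, 1000, 1000), fig1_params)
        np.testing.assert_allclose(fin_pay, inf_pay, atol=1e-2)

    def test_population_smaller_than_group_rejected(self, fig1_params):
        with pytest.raises(ValueError, match="group size"):
            finite_expected_payoffs(PopulationCounts(2, 1, 1, 0), fig1_params)


class TestFermiAndTransitions:
    def test_fermi_basics(self):
        assert fermi(0.0, 2.0) == pytest.approx(0.5)
        assert fermi(123.4, 0.0) == pytest.approx(0.5)
        assert fermi(5.0, 1000.0) == pytest.approx(1.0)
        assert fermi(-5.0, 1000.0) == pytest.approx(0.0)
        d = np.linspace(-3, 3, 13)
        assert np.all(np.diff(fermi(d, 2.0)) > 0)

    def test_transition_boundaries_and_neutral_value(self, fig1_params):
        p = fig1_params
        N = 20
        assert pairwise_transition(
            PopulationCounts(0, N, 0, 0), Strategy.C, Strategy.D, p, 2.0
        ) == 0.0
        # neutral C vs P (no defectors): tau = (n/N)((N-n)/N)/2
        n = 7
        tau = pairwise_transition(
            PopulationCounts(n, 0, N - n, 0), Strategy.C, Strategy.P, p, 2.0
        )
        assert tau == pytest.approx(n / N * (N - n) / N * 0.5)

    def test_detailed_balance_ratio(self, fig1_params):
        """tau_{i->j} / tau_{j->i} = exp[s (P_j - P_i)]."""
        p = fig1_params
        N, s = 30, 1.3
        counts = PopulationCounts(0, 12, 18, 0)
        pay = finite_expected_payoffs(counts, p)
        t_dp = pairwise_transition(counts, Strategy.D, Strategy.P, p, s)
        t_pd = pairwise_transition(counts, Strategy.P, Strategy.D, p, s)
        want = np.exp(s * (pay[Strategy.P] - pay[Strategy.D]))
        assert t_dp / t_pd == pytest.approx(want, rel=1e-12)


class TestFixation:
    def test_neutral_fixation_is_one_over_N(self, fig1_params):
        for N in (6, 10, 50):
            for i, j in [(Strategy.C, Strategy.D), (Strategy.D, Strategy.P), (Strategy.P, Strategy.M)]:
                assert fixation_probability(i, j, fig1_params, N, 0.0) == pytest.approx(
                    1.0 / N, abs=1e-14
                )
        # C vs P are payoff-neutral even at s > 0
        assert fixation_probability(
            Strategy.C, Strategy.P, fig1_params, 40, 2.0
        ) == pytest.approx(1.0 / 40)

    @pytest.mark.parametrize("N", [6, 10, 50, 100])
    @pytest.mark.parametrize("s", [0.0, 0.5, 2.0])
    def test_product_and_expsum_forms_agree(self, fig1_params, N, s):
        """The telescoped product form and the exponent-sum form are the same number."""
        for i, j in [(Strategy.D, Strategy.P), (Strategy.P, Strategy.D), (Strategy.C, Strategy.M)]:
            a = fixation_probability(i, j, fig1_params, N, s, method="product")
            b = fixation_probability(i, j, fig1_params, N, s, method="exp_sum")
            assert abs(a - b) < 1e-10

    def test_against_absorbing_chain_oracle(self, fig1_params):
        """Fixation equals the absorption probability of the exact birth-death chain (N=6)."""
        p = fig1_params
        N, s = 6, 2.0
        resident, mutant = Strategy.D, Strategy.P
        # build the (N+1)-state tridiagonal chain over the mutant count and
        # solve the absorption system h_k = up_k h_{k+1} + down_k h_{k-1} + stay_k h_k
        A = np.zeros((N + 1, N + 1))
        b = np.zeros(N + 1)
        A[0, 0] = 1.0
        A[N, N] = 1.0
        b[N] = 1.0
        for k in range(1, N):
            m = [0, 0, 0, 0]
            m[resident] = N - k
            m[mutant] = k
            counts = PopulationCounts(*m)
            up = pairwise_transition(counts, resident, mutant, p, s)
            down = pairwise_transition(counts, mutant, resident, p, s)
            A[k, k] = up + down
            A[k, k + 1] = -up
            A[k, k - 1] = -down
        h = np.linalg.solve(A, b)
        assert fixation_probability(resident, mutant, p, N, s) == pytest.approx(
            h[1], abs=1e-12
        )


class TestEmbeddedChain:
    def test_rows_sum_to_one_and_nonnegative(self, fig1_params):
        for s in (0.0, 2.0):
            P, pi, red = embedded_markov_chain(fig1_params, 20, s)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_neutral_chain_uniform_stationary(self, fig1_params):
        P, pi, red = embedded_markov_chain(fig1_params, 12, 0.0)
        off = P[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / (3 * 12), atol=1e-14)
        np.testing.assert_allclose(pi, 0.25, atol=1e-10)

    def test_converges_to_strong_imitation_limit(self, fig1_params):
        """Finite-s chains approach the analytic strong-imitation matrix monotonically."""
        N = 100
        target = strong_imitation_matrix(N)
        errs = []
        for s in (10.0, 50.0, 200.0):
            P, _, _ = embedded_markov_chain(fig1_params, N, s)
            errs.append(np.abs(P - target).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_strong_imitation_stationary_all_defect(self):
        """The s -> infinity chain concentrates on the all-defector state: tragedy of the commons."""
        pi, reducible = stationary_distribution(strong_imitation_matrix(100))
        np.testing.assert_allclose(pi, [0, 1, 0, 0], atol=1e-12)


class TestIndividualBasedSimulation:
    def test_mu_zero_homogeneous_absorbing(self, fig1_params):
        evo = EvoParams(s=2.0, mu=0.0, n_steps=2000, seed=5)
        series = simulate_wellmixed(fig1_params, evo, PopulationCounts(0, 0, 50, 0))
        assert np.all(series == [0, 0, 50, 0])

    def test_mu_one_equalizes_frequencies(self, fig1_params):
        evo = EvoParams(s=2.0, mu=1.0, n_steps=30_000, seed=6)
        series = simulate_wellmixed(
            fig1_params, evo, PopulationCounts(60, 0, 0, 0), mutation_mode="switch_other"
        )
        freqs = series[10_000:].mean(axis=0) / 60
        np.testing.assert_allclose(freqs, 0.25, atol=0.03)

    def test_seed_determinism(self, fig1_params):
        evo = EvoParams(s=2.0, mu=1e-2, n_steps=3000, seed=11)
        a = simulate_wellmixed(fig1_params, evo, PopulationCounts(10, 10, 10, 10))
        b = simulate_wellmixed(fig1_params, evo, PopulationCounts(10, 10, 10, 10))
        np.testing.assert_array_equal(a, b)

    def test_low_threshold_prolongs_cooperative_quasi_state(self, fig1_params, fig1_params_h3):
        """The defector-suppressed quasi-stable state lasts longer for H=1 than H=3."""
        def suppressed_fraction(params, seed):
            evo = EvoParams(s=2.0, mu=1e-3, n_steps=40_000, seed=seed)
            series = simulate_wellmixed(params, evo, PopulationCounts(25, 25, 25, 25))
            return np.mean(series[:, Strategy.D] < 10)

        h1 = np.mean([suppressed_fraction(fig1_params, seed) for seed in range(5)])
        h3 = np.mean([suppressed_fraction(fig1_params_h3, seed) for seed in range(5)])
        assert h1 > h3
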