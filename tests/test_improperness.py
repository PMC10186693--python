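"""Improperness conditions, the simplex grid search, the counterfactual
feasibility screen, and the Beta continuous-covariate extension."""

import warnings

import numpy as np
import pytest

from cfbaudit import (
    BetaMixingPopulation,
    ProbabilityTriple,
    cfb_star_beta,
    cfb_star_binary,
    counterfactual_feasibility,
    grid_search,
    satisfies_discordance_dominance,
    satisfies_ordering,
)
from conftest import random_triple

BREAST_P = ProbabilityTriple(0.25, 0.01, 0.74)
BREAST_Q = ProbabilityTriple(0.14, 0.18, 0.68)
MIN_P = ProbabilityTriple(0.03, 0.0, 0.97)
MIN_Q = ProbabilityTriple(0.0, 0.06, 0.94)


class TestConditions:
    def test_ordering_worked_example(self):
        assert satisfies_ordering(BREAST_P, BREAST_Q)  # 0.54 > 0.49

    def test_ordering_requires_strictness(self):
        t = ProbabilityTriple(0.2, 0.3, 0.5)
        assert not satisfies_ordering(t, t)
        # the printed minimizing pair ties on mean benefit (0.94 both ways)
        assert not satisfies_ordering(MIN_P, MIN_Q)
        assert not satisfies_ordering(MIN_Q, MIN_P)

    def test_dominance_worked_example(self):
        assert satisfies_discordance_dominance(BREAST_P, BREAST_Q)

    def test_dominance_fails_on_equal_triples(self):
        t = ProbabilityTriple(0.2, 0.3, 0.5)
        assert not satisfies_discordance_dominance(t, t)

    def test_dominance_fails_under_strong_stochastic_dominance(self):
        assert not satisfies_discordance_dominance(
            ProbabilityTriple(1.0, 0.0, 0.0), ProbabilityTriple(0.0, 0.0, 1.0)
        )

    def test_printed_inequality_form_agrees_with_summation_form(self, rng):
        # q₊ − q₋ + q₋p₊ < p₊ − p₋ + q₊p₋  ⟺  Σ_{a>b} q_a p_b < Σ_{a<b} q_a p_b
        for _ in range(200):
            p, q = random_triple(rng), random_triple(rng)
            printed = (
                q.p_plus - q.p_minus + q.p_minus * p.p_plus
                < p.p_plus - p.p_minus + q.p_plus * p.p_minus
            )
            assert printed == satisfies_discordance_dominance(p, q)

    def test_conditions_equivalent_to_improper_cfb(self, rng):
        # for strictly ordered pairs: both conditions hold ⟺ cfb* < 0.5,
        # with the exact table computation as the independent arbiter
        checked = 0
        while checked < 300:
            p, q = random_triple(rng), random_triple(rng)
            if not satisfies_ordering(p, q):
                continue
            both = satisfies_discordance_dominance(p, q)
            value = cfb_star_binary(p, q)
            assert both == (value < 0.5)
            checked += 1


@pytest.fixture(scope="module")
def coarse():
    return grid_search(step=0.05)


class TestGridSearch:
    def test_all_retained_below_half(self, coarse):
        assert coarse.count > 0
        assert np.all(coarse.cfb_star_values < 0.5)

    def test_retained_pairs_satisfy_conditions(self, coarse):
        for i in range(0, coarse.count, max(1, coarse.count // 50)):
            p = ProbabilityTriple(*coarse.p_triples[i])
            q = ProbabilityTriple(*coarse.q_triples[i])
            assert satisfies_discordance_dominance(p, q)
            assert q.mean_benefit >= p.mean_benefit - 1e-12

    def test_values_match_direct_table_computation(self, coarse):
        for i in range(0, coarse.count, max(1, coarse.count // 25)):
            p = ProbabilityTriple(*coarse.p_triples[i])
            q = ProbabilityTriple(*coarse.q_triples[i])
            assert coarse.cfb_star_values[i] == pytest.approx(
                cfb_star_binary(p, q), abs=1e-10
            )

    @pytest.mark.parametrize("step", [0.1, 0.05, 0.02])
    def test_binary_benefit_restriction_is_empty(self, step):
        assert grid_search(step=step, binary_b=True).count == 0

    def test_summary_and_frame_shape(self, coarse):
        s = coarse.summary
        assert s["count"] == coarse.count
        assert s["min"] <= s["median"] <= s["max"] < 0.5
        df = coarse.to_frame()
        assert list(df.columns) == [
            "p_minus", "p_zero", "p_plus", "q_minus", "q_zero", "q_plus", "cfb_star",
        ]
        assert len(df) == coarse.count


class TestCounterfactualFeasibility:
    def test_deterministic_benefit(self):
        feasible, pair = counterfactual_feasibility(ProbabilityTriple(0, 0, 1))
        assert feasible and pair == pytest.approx((0.0, 1.0))

    def test_symmetric_half_triple(self):
        feasible, pair = counterfactual_feasibility(ProbabilityTriple(0.25, 0.5, 0.25))
        assert feasible and pair == pytest.approx((0.5, 0.5))

    def test_no_zero_mass_with_both_tails(self):
        feasible, pair = counterfactual_feasibility(ProbabilityTriple(0.5, 0.0, 0.5))
        assert not feasible and pair is None

    def test_constructed_triples_always_feasible(self, rng):
        # triples literally generated by independent Bernoullis must screen feasible
        for _ in range(300):
            pi0, pi1 = rng.random(2)
            t = ProbabilityTriple(
                pi0 * (1 - pi1), pi0 * pi1 + (1 - pi0) * (1 - pi1), pi1 * (1 - pi0)
            )
            feasible, pair = counterfactual_feasibility(t)
            assert feasible
            r0, r1 = pair
            assert r1 * (1 - r0) == pytest.approx(t.p_plus, abs=1e-9)
            assert r0 * (1 - r1) == pytest.approx(t.p_minus, abs=1e-9)

    def test_agrees_with_grid_oracle(self, rng):
        # exhaustive (π0, π1) grid at resolution 0.002; skip borderline residuals
        grid = np.linspace(0.0, 1.0, 501)
        g0, g1 = np.meshgrid(grid, grid, indexing="ij")
        checked = 0
        for _ in range(400):
            t = random_triple(rng)
            resid = np.maximum(
                np.abs(g1 * (1 - g0) - t.p_plus), np.abs(g0 * (1 - g1) - t.p_minus)
            ).min()
            feasible, _ = counterfactual_feasibility(t)
            if resid < 1e-4:
                assert feasible
                checked += 1
            elif resid > 5e-3:
                assert not feasible
                checked += 1
        assert checked > 200  # most draws are far from the feasibility boundary


class TestBetaMixing:
    def test_identical_triples_return_half_with_warning(self):
        pop = BetaMixingPopulation(BREAST_P, BREAST_P, epsilon=0.5)
        with pytest.warns(UserWarning, match="identical triples"):
            assert cfb_star_beta(pop) == 0.5

    def test_requires_positive_epsilon(self):
        with pytest.raises(ValueError):
            BetaMixingPopulation(BREAST_P, BREAST_Q, epsilon=0.0)

    def test_monotone_convergence_to_binary_value(self):
        binary = cfb_star_binary(BREAST_P, BREAST_Q)
        values = [
            cfb_star_beta(BetaMixingPopulation(BREAST_P, BREAST_Q, eps))
            for eps in (1.0, 0.1, 0.01, 0.001)
        ]
        gaps = [abs(v - binary) for v in values]
        assert gaps == sorted(gaps, reverse=True)  # monotone approach
        assert gaps[-1] < 0.005
        assert all(v < 0.5 for v in values)

    def test_quadrature_agrees_with_monte_carlo(self, rng):
        for eps in (1.0, 0.01):
            pop = BetaMixingPopulation(BREAST_P, BREAST_Q, eps)
            quad = cfb_star_beta(pop, method="quadrature")
            n = 200_000
            mc = cfb_star_beta(pop, method="monte-carlo", n_or_nodes=n,
                               seed=int(rng.integers(2**31)))
            # ≈ 2·0.2244·n informative pairs; 3 nominal binomial SE
            se = np.sqrt(0.25 / (2 * 0.2244 * n))
            assert abs(mc - quad) <= 3 * se

    def test_monte_carlo_requires_seed(self):
        pop = BetaMixingPopulation(BREAST_P, BREAST_Q, 0.5)
        with pytest.raises(ValueError, match="seed"):
            cfb_star_beta(pop, method="monte-carlo")

    def test_decreasing_slope_orientation(self):
        # swapping the triples flips the predictor's slope, not the value
        a = cfb_star_beta(BetaMixingPopulation(BREAST_P, BREAST_Q, 0.2))
        b = cfb_star_beta(BetaMixingPopulation(BREAST_Q, BREAST_P, 0.2))
        assert a == pytest.approx(b, abs=1e-12)
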