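"""Matched-population construction from a logistic RCT and its effect on cfb.

In a parallel-arm trial the benefit B is never observed directly; the original
cfb proposal replaces it with the observed benefit of a matched treated/control
pair — the treated outcome minus the control outcome. Matching can be done on
the covariate pattern X or on the predicted benefit H = h(X). When h is not a
bijection the two definitions induce different distributions of (B̂ | H) and
hence different cfb values for the same predictor in the same source
population; this module constructs both matched populations exactly (infinite
population) and sweeps random source populations to quantify the discrepancy.

Source population: ternary covariate X ∈ {0, 1, 2} with masses (a, b, 1−a−b),
treatment assigned with probability 1/2 independently of X, and

    logit Pr(Y=1 | T, X) = β0 + βx X + βt T + βxt T X.

Two sampling schemes for the matched pairs are supported: ``sequential``
(draw a treated patient, then a control with the same matching value) keeps
the covariate marginal of the source population; ``joint-conditional`` (draw
two patients and condition on equal matching values and opposite arms)
re-weights each matching level by the square of its mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit

from .populations import (
    BenefitPredictor,
    DiscreteBenefitPopulation,
    ProbabilityTriple,
    pair_table,
)
from .metrics import CfbResult, cfb_from_table

__all__ = [
    "LogisticRCTPopulation",
    "MatchedPopulation",
    "default_benefit_predictor",
    "outcome_prob",
    "matched_population",
    "matching_difference",
    "matching_sweep",
]

_TOL = 1e-12

#: The worked non-bijective predictor h(x) = x² − x − 1, H ∈ {−1, 1} on {0, 1, 2}.
default_benefit_predictor = BenefitPredictor({x: x**2 - x - 1 for x in (0, 1, 2)})


@dataclass(frozen=True)
class LogisticRCTPopulation:
    """RCT source population: ternary covariate and a logistic outcome model."""

    a: float
    b: float
    beta_0: float
    beta_x: float
    beta_t: float
    beta_xt: float

    def __post_init__(self) -> None:
        if self.a < -_TOL or self.b < -_TOL or self.a + self.b > 1.0 + _TOL:
            raise ValueError("require a, b ≥ 0 and a + b ≤ 1")

    @property
    def covariate_masses(self) -> dict[int, float]:
        """Masses of levels {0, 1, 2}; zero-mass levels are dropped."""
        masses = {0: self.a, 1: self.b, 2: 1.0 - self.a - self.b}
        return {x: m for x, m in masses.items() if m > _TOL}


def outcome_prob(pop: LogisticRCTPopulation, t: int, x: int) -> float:
    """Pr(Y = 1 | T = t, X = x) = logit⁻¹(β0 + βx x + βt t + βxt t x)."""
    return float(expit(pop.beta_0 + pop.beta_x * x + pop.beta_t * t + pop.beta_xt * t * x))


def _pair_triple(pi1: float, pi0: float) -> ProbabilityTriple:
    """Observed-benefit triple of a treated/control pair with success probs (π1, π0)."""
    return ProbabilityTriple(
        p_minus=pi0 * (1.0 - pi1),
        p_zero=pi1 * pi0 + (1.0 - pi1) * (1.0 - pi0),
        p_plus=pi1 * (1.0 - pi0),
    )


@dataclass(frozen=True)
class MatchedPopulation:
    """Exact matched population: per matching level, a prediction value, the
    observed-benefit triple, and the level's probability mass."""

    h_values: tuple
    triples: tuple
    masses: tuple
    provenance: dict = field(compare=False)

    def to_benefit_population(self) -> tuple[DiscreteBenefitPopulation, BenefitPredictor]:
        levels = tuple(range(len(self.h_values)))
        pop = DiscreteBenefitPopulation(levels, self.masses, self.triples)
        h = BenefitPredictor(dict(zip(levels, self.h_values)))
        return pop, h

    def cfb(self) -> CfbResult:
        pop, h = self.to_benefit_population()
        return cfb_from_table(pair_table(pop, h))


def matched_population(
    pop: LogisticRCTPopulation,
    h: BenefitPredictor = default_benefit_predictor,
    match_on: Literal["X", "H"] = "X",
    scheme: Literal["sequential", "joint-conditional"] = "sequential",
) -> MatchedPopulation:
    """Exact matched population under a matching criterion and sampling scheme.

    Matching on X: a pair at level x combines one treated and one control
    patient with success probabilities π1(x) and π0(x). Matching on H: a pair
    at prediction value v draws treated and control covariates independently
    from Pr(X | h(X) = v) (the arm-free source conditional, by randomization),
    then mixes the Bernoulli pair probabilities over (x₁, x₂).

    The ``sequential`` scheme weights each matching level by its source mass;
    ``joint-conditional`` weights it by the squared mass, renormalized.
    """
    masses = pop.covariate_masses
    pi1 = {x: outcome_prob(pop, 1, x) for x in masses}
    pi0 = {x: outcome_prob(pop, 0, x) for x in masses}

    if match_on == "X":
        levels = sorted(masses)
        h_vals = [h(x) for x in levels]
        triples = [_pair_triple(pi1[x], pi0[x]) for x in levels]
        level_mass = np.array([masses[x] for x in levels])
    elif match_on == "H":
        by_h: dict[float, list[int]] = {}
        for x in sorted(masses):
            by_h.setdefault(h(x), []).append(x)
        h_vals = sorted(by_h)
        triples = []
        level_mass = []
        for v in h_vals:
            xs = by_h[v]
            total = sum(masses[x] for x in xs)
            if len(xs) == 1:
                # singleton preimage: identical to matching on X at this level
                triples.append(_pair_triple(pi1[xs[0]], pi0[xs[0]]))
            else:
                cond = {x: masses[x] / total for x in xs}
                # independent treated (x1) and control (x2) draws given h(X) = v
                plus = sum(
                    cond[x1] * cond[x2] * pi1[x1] * (1.0 - pi0[x2])
                    for x1 in xs for x2 in xs
                )
                minus = sum(
                    cond[x1] * cond[x2] * pi0[x2] * (1.0 - pi1[x1])
                    for x1 in xs for x2 in xs
                )
                triples.append(ProbabilityTriple(minus, 1.0 - plus - minus, plus))
            level_mass.append(total)
        level_mass = np.array(level_mass)
    else:
        raise ValueError(f"unknown matching criterion {match_on!r}")

    if scheme == "joint-conditional":
        level_mass = level_mass**2
    elif scheme != "sequential":
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    level_mass = level_mass / level_mass.sum()

    return MatchedPopulation(
        h_values=tuple(h_vals),
        triples=tuple(triples),
        masses=tuple(level_mass),
        provenance={"match_on": match_on, "scheme": scheme},
    )


def matching_difference(
    pop: LogisticRCTPopulation,
    h: BenefitPredictor = default_benefit_predictor,
    scheme: Literal["sequential", "joint-conditional"] = "sequential",
) -> float:
    """|cfb(match on X) − cfb(match on H)| for the same predictor and scheme."""
    cfb_x = matched_population(pop, h, match_on="X", scheme=scheme).cfb().value
    cfb_h = matched_population(pop, h, match_on="H", scheme=scheme).cfb().value
    return abs(cfb_x - cfb_h)


def matching_sweep(
    n_combos: int = 10_000,
    grid_step_ab: float = 0.01,
    beta_range: tuple[float, float] = (-5.0, 5.0),
    seed: int = 0,
    h: BenefitPredictor = default_benefit_predictor,
    scheme: Literal["sequential", "joint-conditional"] = "sequential",
) -> pd.DataFrame:
    """Seeded sweep of random source populations recording |Δcfb| per combination.

    (a, b) is sampled uniformly from the ``grid_step_ab`` grid points with
    0 < a + b < 1; the four logistic coefficients are drawn independently from
    the uniform distribution on ``beta_range``. Returns one row per combination
    with the two cfb values and their absolute difference.
    """
    rng = np.random.default_rng(seed)
    k = round(1.0 / grid_step_ab)
    grid = [
        (i * grid_step_ab, j * grid_step_ab)
        for i in range(k + 1)
        for j in range(k + 1 - i)
        if 0 < i + j < k
    ]
    idx = rng.integers(0, len(grid), size=n_combos)
    lo, hi = beta_range
    betas = rng.uniform(lo, hi, size=(n_combos, 4))

    rows = []
    for m in range(n_combos):
        a, b = grid[idx[m]]
        pop = LogisticRCTPopulation(a, b, *betas[m])
        cfb_x = matched_population(pop, h, match_on="X", scheme=scheme).cfb().value
        cfb_h = matched_population(pop, h, match_on="H", scheme=scheme).cfb().value
        rows.append(
            {
                "a": a,
                "b": b,
                "beta_0": betas[m, 0],
                "beta_x": betas[m, 1],
                "beta_t": betas[m, 2],
                "beta_xt": betas[m, 3],
                "cfb_match_x": cfb_x,
                "cfb_match_h": cfb_h,
                "abs_diff": abs(cfb_x - cfb_h),
            }
        )
    return pd.DataFrame(rows)
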