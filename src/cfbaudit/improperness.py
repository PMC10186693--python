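"""Improperness machinery for the concordance statistic for benefit.

A scoring rule for benefit predictors is proper when the true conditional-mean
predictor h*(x) = E[B | X = x] attains the best score. For a binary covariate
X with Pr(X=1) = 1/2 and per-stratum benefit triples p (X=0) and q (X=1), the
true predictor scores below a random guess (cfb* < 1/2) exactly when two
algebraic conditions hold simultaneously:

* ordering:      q₊ − q₋ > p₊ − p₋        (h* labels X=1 the better stratum)
* discordance:   Σ_{a>b} q_a p_b < Σ_{a<b} q_a p_b
                 ⟺  q₊ − q₋ + q₋ p₊ < p₊ − p₋ + q₊ p₋

This module enumerates the simplex grid of triple pairs satisfying both
conditions (the improperness search), screens triples for compatibility with
conditionally independent counterfactual Bernoulli outcomes, and extends the
binary-X construction to a continuous X ~ Beta(ε, ε) whose conditional benefit
distribution linearly interpolates the two triples — the binary population is
recovered in the limit ε ↓ 0.

When the two strata have equal h* values (the ordering condition holds with
equality), the strata are still treated as distinct prediction groups: the
pair-relation table is formed with the stratum labels breaking the tie, and of
the two possible labelings the one yielding cfb* < 1/2 is retained. This is
the labeling under which the known minimizing grid pairs evaluate below 1/2;
the direct table computation is the arbiter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .populations import (
    BenefitPredictor,
    DiscreteBenefitPopulation,
    ProbabilityTriple,
    pair_table,
)
from .metrics import cfb_from_table

__all__ = [
    "satisfies_ordering",
    "satisfies_discordance_dominance",
    "cfb_star_binary",
    "ImproperSearchResult",
    "grid_search",
    "counterfactual_feasibility",
    "BetaMixingPopulation",
    "cfb_star_beta",
]

_TOL = 1e-12


def satisfies_ordering(p: ProbabilityTriple, q: ProbabilityTriple) -> bool:
    """Strict ordering condition: q₊ − q₋ > p₊ − p₋ (h*(1) > h*(0))."""
    return q.mean_benefit > p.mean_benefit + _TOL


def _concordance_masses(p: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """(Σ_{a>b} q_a p_b, Σ_{a<b} q_a p_b) over benefit levels ordered (−1, 0, +1)."""
    conc = q[1] * p[0] + q[2] * p[0] + q[2] * p[1]
    disc = q[0] * p[1] + q[0] * p[2] + q[1] * p[2]
    return float(conc), float(disc)


def satisfies_discordance_dominance(p: ProbabilityTriple, q: ProbabilityTriple) -> bool:
    """Discordance-dominance condition: Σ_{a>b} q_a p_b < Σ_{a<b} q_a p_b.

    Algebraically equivalent to q₊ − q₋ + q₋ p₊ < p₊ − p₋ + q₊ p₋.
    """
    conc, disc = _concordance_masses(p.as_array(), q.as_array())
    return conc < disc - _TOL


def cfb_star_binary(
    p: ProbabilityTriple,
    q: ProbabilityTriple,
    x1_prob: float = 0.5,
    distinct_strata: bool = True,
) -> float:
    """Exact cfb of the true predictor for the two-stratum population (p at X=0, q at X=1).

    With ``distinct_strata`` (default) the two strata are treated as distinct
    prediction groups even when their h* values coincide, i.e. the pair table
    is indexed by the stratum label; with strictly ordered h* values this is
    identical to indexing by h* itself.
    """
    h = BenefitPredictor({0: 0.0, 1: 1.0}) if distinct_strata else None
    pop = DiscreteBenefitPopulation([0, 1], [1 - x1_prob, x1_prob], [p, q])
    if h is None:
        from .populations import true_predictor

        h = true_predictor(pop)
    return cfb_from_table(pair_table(pop, h)).value


def _simplex_grid(step: float, binary_b: bool = False) -> np.ndarray:
    """All probability triples with components on the step-grid of the 2-simplex."""
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    rows = []
    for i in range(k + 1):
        for j in range(k + 1 - i):
            if binary_b and j != 0:
                continue
            rows.append((i * step, j * step, (k - i - j) * step))
    return np.asarray(rows)


@dataclass
class ImproperSearchResult:
    """Triple pairs on the simplex grid for which the true predictor is improper.

    ``p_triples``/``q_triples`` are (N, 3) arrays ordered (p₋, p₀, p₊); each
    stored pair satisfies the ordering condition (non-strictly, equality
    resolved by the distinct-strata labeling) and the strict discordance
    condition, and each ``cfb_star_values`` entry is below 0.5.
    """

    p_triples: np.ndarray = field(repr=False)
    q_triples: np.ndarray = field(repr=False)
    cfb_star_values: np.ndarray = field(repr=False)
    step: float = 0.01
    x1_prob: float = 0.5

    @property
    def count(self) -> int:
        return int(self.cfb_star_values.size)

    @property
    def summary(self) -> dict:
        if self.count == 0:
            return {"count": 0, "min": None, "max": None, "median": None}
        v = self.cfb_star_values
        return {
            "count": self.count,
            "min": float(v.min()),
            "max": float(v.max()),
            "median": float(np.median(v)),
        }

    def argmin_pair(self) -> tuple[ProbabilityTriple, ProbabilityTriple]:
        i = int(np.argmin(self.cfb_star_values))
        return (
            ProbabilityTriple(*self.p_triples[i]),
            ProbabilityTriple(*self.q_triples[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for name, arr in (("p", self.p_triples), ("q", self.q_triples)):
            for j, suffix in enumerate(("minus", "zero", "plus")):
                cols[f"{name}_{suffix}"] = arr[:, j]
        cols["cfb_star"] = self.cfb_star_values
        return pd.DataFrame(cols)


def grid_search(
    step: float = 0.01,
    x1_prob: float = 0.5,
    binary_b: bool = False,
    chunk: int = 256,
) -> ImproperSearchResult:
    """Brute-force enumeration of improper triple pairs on the simplex grid.

    Enumerates every ordered pair of triples with components on the ``step``
    grid, retains pairs satisfying the ordering condition (with equality
    allowed, resolved by the distinct-strata labeling) together with the strict
    discordance condition, and records the exact cfb* of each retained pair.
    With ``binary_b`` the no-effect mass is forced to zero in both triples
    (classical binary-outcome c-statistic setting); no pair then qualifies.
    """
    if not (0 < step <= 0.5):
        raise ValueError("step must lie in (0, 0.5]")
    tri = _simplex_grid(step, binary_b=binary_b)
    pm, p0, pp = tri.T
    h = pp - pm
    tie_within = (1.0 - (tri**2).sum(axis=1)) / 2.0  # Σ_{a>b} t_a t_b per triple
    w0 = 1.0 - x1_prob
    w1 = x1_prob

    ps, qs, vals = [], [], []
    for s in range(0, len(tri), chunk):
        qm, q0, qp = pm[s : s + chunk, None], p0[s : s + chunk, None], pp[s : s + chunk, None]
        conc = q0 * pm[None, :] + qp * pm[None, :] + qp * p0[None, :]
        disc = qm * p0[None, :] + qm * pp[None, :] + q0 * pp[None, :]
        ok = (h[s : s + chunk, None] >= h[None, :] - _TOL) & (conc < disc - _TOL)
        if not ok.any():
            continue
        tie = w0 * w0 * tie_within[None, :] + w1 * w1 * tie_within[s : s + chunk, None]
        num = (w0 * w1 * conc + 0.5 * tie)[ok]
        den = (w0 * w1 * (conc + disc) + tie)[ok]
        qi, pi = np.nonzero(ok)
        ps.append(tri[pi])
        qs.append(tri[s + qi])
        vals.append(num / den)
    if vals:
        p_arr, q_arr, v_arr = np.vstack(ps), np.vstack(qs), np.concatenate(vals)
    else:
        p_arr = q_arr = np.empty((0, 3))
        v_arr = np.empty(0)
    return ImproperSearchResult(p_arr, q_arr, v_arr, step=step, x1_prob=x1_prob)


def counterfactual_feasibility(
    t: ProbabilityTriple, tol: float = 1e-9
) -> tuple[bool, tuple[float, float] | None]:
    """Can ``t`` arise from conditionally independent Bernoulli counterfactuals?

    Seeks π0 = Pr(Y(0)=1), π1 = Pr(Y(1)=1) in [0, 1] with
    π1(1−π0) = p₊ and π0(1−π1) = p₋ (the no-effect mass is then automatic).
    Eliminating π1 = π0 + (p₊ − p₋) reduces the system to the quadratic
    π0² − (1 − d) π0 + p₋ = 0 with d = p₊ − p₋, solved in closed form.

    Returns ``(True, (π0, π1))`` with a solving pair, or ``(False, None)``.
    """
    d = t.p_plus - t.p_minus
    # π0² − (1 − d) π0 + p₋ = 0
    b = 1.0 - d
    disc = b * b - 4.0 * t.p_minus
    if disc < -tol:
        return False, None
    disc = max(disc, 0.0)
    for root in ((b - np.sqrt(disc)) / 2.0, (b + np.sqrt(disc)) / 2.0):
        pi0 = min(max(float(root), 0.0), 1.0)
        pi1 = pi0 + d
        if not (-tol <= pi1 <= 1.0 + tol):
            continue
        pi1 = min(max(pi1, 0.0), 1.0)
        if (
            abs(pi1 * (1 - pi0) - t.p_plus) <= tol
            and abs(pi0 * (1 - pi1) - t.p_minus) <= tol
        ):
            return True, (pi0, pi1)
    return False, None


@dataclass(frozen=True)
class BetaMixingPopulation:
    """Continuous-X population: X ~ Beta(ε, ε), Pr(B=i | X=x) = p_i + (q_i − p_i) x.

    Convexity guarantees the interpolated triple is valid for every x in [0, 1].
    As ε ↓ 0 the Beta mass concentrates on {0, 1} and the two-stratum binary-X
    population with Pr(X=1) = 1/2 is recovered.
    """

    p: ProbabilityTriple
    q: ProbabilityTriple
    epsilon: float

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    def conditional_triples(self, x: np.ndarray) -> np.ndarray:
        p, q = self.p.as_array(), self.q.as_array()
        return p[None, :] + np.asarray(x)[..., None] * (q - p)[None, :]


def cfb_star_beta(
    pop: BetaMixingPopulation,
    method: Literal["quadrature", "monte-carlo"] = "quadrature",
    n_or_nodes: int | None = None,
    seed: int | None = None,
) -> float:
    """cfb of the true predictor under Beta(ε, ε) covariate mixing.

    The true predictor h*(x) = (p₊ − p₋) + [(q₊ − q₋) − (p₊ − p₋)] x is strictly
    monotone in x whenever the triples differ in mean benefit, so prediction
    ties have probability zero and

        cfb* = Pr(h*(X1) > h*(X2), B1 > B2) / Pr(B1 > B2).

    ``quadrature`` evaluates this exactly up to 1-D quadrature error: the
    numerator is bilinear in (X1, X2) on the half-plane X1 > X2, so it reduces
    to moments of Beta(ε, ε) plus E|X1 − X2| = ∫ 2F(1−F), which is integrated
    adaptively. ``monte-carlo`` simulates ``n_or_nodes`` pairs (default 10⁵;
    ``seed`` required) and scores floating-point X ties as 0.5 — at very small
    ε Beta samples round to exactly 0 or 1, and the half-credit score is the
    correct binary-limit behavior.

    Identical triples make h* constant; by the all-ties convention the value
    is 0.5, returned with a warning.
    """
    p, q = pop.p.as_array(), pop.q.as_array()
    delta = q - p
    slope = pop.q.mean_benefit - pop.p.mean_benefit
    if np.allclose(p, q, atol=_TOL):
        warnings.warn("identical triples: h* is constant, returning cfb = 0.5 (all ties)")
        return 0.5
    if method == "monte-carlo":
        if seed is None:
            raise ValueError("monte-carlo method requires a seed")
        n = n_or_nodes or 100_000
        rng = np.random.default_rng(seed)
        x = rng.beta(pop.epsilon, pop.epsilon, size=(n, 2))
        probs = pop.conditional_triples(x)  # (n, 2, 3)
        u = rng.random((n, 2, 1))
        b = (u > probs.cumsum(axis=-1)).sum(axis=-1) - 1  # levels −1, 0, 1
        informative = b[:, 0] != b[:, 1]
        hv = slope * x  # monotone transform of h*, same order relations
        prod = (b[:, 0] - b[:, 1]) * (hv[:, 0] - hv[:, 1])
        score = np.where(prod > 0, 1.0, np.where(hv[:, 0] == hv[:, 1], 0.5, 0.0))
        if not informative.any():
            warnings.warn("no informative pairs sampled, returning 0.5")
            return 0.5
        return float(score[informative].mean())
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")

    F = stats.beta(pop.epsilon, pop.epsilon).cdf
    e_abs_diff, _ = integrate.quad(lambda x: 2.0 * F(x) * (1.0 - F(x)), 0.0, 1.0, limit=200)
    e_max = 0.5 + e_abs_diff / 2.0
    e_min = 0.5 - e_abs_diff / 2.0
    # orientation: h* increasing in x ⇒ concordance region is X1 > X2
    m1, m2 = (e_max, e_min) if slope > 0 else (e_min, e_max)
    # E[P_a(X1) P_b(X2) 1{h(X1)>h(X2)}] with P_i(x) = p_i + delta_i x:
    #   p_a p_b /2 + p_a delta_b m2/2 + delta_a p_b m1/2 + delta_a delta_b E[X1 X2]/2
    mbar = (p + q) / 2.0  # E[P_i(X)] since E[X] = 1/2
    num = den = 0.0
    for a in range(3):
        for b_ in range(a):
            num += (
                p[a] * p[b_] / 2.0
                + p[a] * delta[b_] * m2 / 2.0
                + delta[a] * p[b_] * m1 / 2.0
                + delta[a] * delta[b_] / 8.0
            )
            den += mbar[a] * mbar[b_]
    return float(num / den)
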