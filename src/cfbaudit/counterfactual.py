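"""Linear-Gaussian counterfactual outcomes and the ρ-sensitivity of cfb.

The model posits continuous potential outcomes linear in a normal covariate:

    Y(t) = α_t + β_t X + ε_t,   X ~ N(0, x_sd²),
    (ε_0, ε_1) bivariate normal, sd (σ0, σ1), correlation ρ.

ρ is the conditional correlation between the two potential outcomes given X.
It is unidentifiable from any observable data — the two outcomes are never
seen on the same patient — yet it shifts the distribution of the benefit
B = Y(1) − Y(0) and hence the value of cfb of the true predictor
H* = E[B | X] = (α1 − α0) + (β1 − β0) X.

Because (B, H*) are jointly normal and pair differences remain normal, cfb*
has the closed form

    cfb* = 1/2 + arcsin(r) / π,     r = sd(H*) / sd(B),
    sd(B)² = sd(H*)² + σ0² + σ1² − 2 ρ σ0 σ1,

nondecreasing in ρ. Thresholding the outcomes (dichotomization) has no such
closed form; a seeded Monte Carlo estimator is provided and the dependence on
ρ persists.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, pi, sqrt

import numpy as np
from scipy.stats import norm

__all__ = [
    "GaussianCounterfactualModel",
    "cfb_star_closed_form",
    "cfb_star_dichotomized",
]


@dataclass(frozen=True)
class GaussianCounterfactualModel:
    """Linear counterfactual outcome model with correlated noise terms.

    ``threshold`` optionally defines dichotomized outcomes 1{Y(t) > threshold}.
    """

    alpha0: float = 0.0
    alpha1: float = 0.0
    beta0: float = 0.0
    beta1: float = 1.0
    sigma0: float = 1.0
    sigma1: float = 1.0
    rho: float = 0.0
    x_sd: float = 1.0
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.sigma1 <= 0 or self.x_sd <= 0:
            raise ValueError("sigma0, sigma1 and x_sd must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [−1, 1]")

    @property
    def benefit_sd(self) -> float:
        """Standard deviation of B = Y(1) − Y(0)."""
        v_h = (self.beta1 - self.beta0) ** 2 * self.x_sd**2
        v_noise = self.sigma0**2 + self.sigma1**2 - 2 * self.rho * self.sigma0 * self.sigma1
        return sqrt(v_h + v_noise)


def cfb_star_closed_form(model: GaussianCounterfactualModel) -> float:
    """Exact cfb of the true predictor for continuous outcomes.

    Returns 1/2 + arcsin(r)/π with r = sd(H*)/sd(B). When β1 = β0 the true
    predictor is constant and 0.5 is returned (all-ties convention); when the
    noise cancels exactly (ρ = 1, σ0 = σ1) then B = H* and the value is 1.
    """
    sd_h = abs(model.beta1 - model.beta0) * model.x_sd
    if sd_h == 0.0:
        return 0.5
    sd_b = model.benefit_sd
    if sd_b == 0.0:  # degenerate: B constant, no informative pairs
        return 0.5
    r = min(sd_h / sd_b, 1.0)
    return 0.5 + asin(r) / pi


def cfb_star_dichotomized(
    model: GaussianCounterfactualModel, n_pairs: int, seed: int
) -> tuple[float, float]:
    """Monte Carlo cfb* for thresholded (binary) outcomes.

    Outcomes are 1{Y(t) > threshold}, the observed benefit is their difference
    in {−1, 0, +1}, and the true predictor is computed analytically per patient:
    H*(x) = Φ((α1 + β1 x − c)/σ1) − Φ((α0 + β0 x − c)/σ0). ``n_pairs``
    independent patient pairs are scored (concordant 1, prediction tie 0.5,
    discordant 0) among pairs with unequal benefit.

    Returns ``(estimate, standard_error)``; if no informative pair occurs the
    degenerate value (0.5, 0.0) is returned.
    """
    if model.threshold is None:
        raise ValueError("model.threshold must be set for dichotomized outcomes")
    if n_pairs < 10_000:
        raise ValueError("n_pairs must be at least 10^4")
    rng = np.random.default_rng(seed)
    c = model.threshold
    x = rng.normal(0.0, model.x_sd, size=(n_pairs, 2))
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [
            [model.sigma0**2, model.rho * model.sigma0 * model.sigma1],
            [model.rho * model.sigma0 * model.sigma1, model.sigma1**2],
        ],
        size=(n_pairs, 2),
    )
    y0 = model.alpha0 + model.beta0 * x + z[..., 0]
    y1 = model.alpha1 + model.beta1 * x + z[..., 1]
    b = (y1 > c).astype(int) - (y0 > c).astype(int)
    h = norm.cdf((model.alpha1 + model.beta1 * x - c) / model.sigma1) - norm.cdf(
        (model.alpha0 + model.beta0 * x - c) / model.sigma0
    )
    informative = b[:, 0] != b[:, 1]
    if not informative.any():
        return 0.5, 0.0
    prod = (b[:, 0] - b[:, 1]) * (h[:, 0] - h[:, 1])
    score = np.where(prod > 0, 1.0, np.where(h[:, 0] == h[:, 1], 0.5, 0.0))[informative]
    est = float(score.mean())
    se = float(score.std(ddof=1) / sqrt(score.size)) if score.size > 1 else 0.0
    return est, se
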