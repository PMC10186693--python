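"""Seeded generators of finite-sample datasets matching the model assumptions.

Every generator is a pure function of (specification, n, seed): identical
calls return identical datasets, with no global random state. Counterfactual
datasets expose both potential outcomes — legitimate in simulation and exactly
what real trial data cannot provide; an observed-data view drops the outcome
of the unassigned arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counterfactual import GaussianCounterfactualModel
from .matching import LogisticRCTPopulation, MatchedPopulation, outcome_prob
from .metrics import MatchedPairRecord

__all__ = [
    "TrialDataset",
    "CounterfactualDataset",
    "sample_trial",
    "sample_counterfactual",
    "sample_matched_pairs",
]


@dataclass(frozen=True)
class TrialDataset:
    """Finite RCT sample with columns (x, t, y) and generating metadata."""

    data: pd.DataFrame = field(repr=False)
    meta: dict = field(compare=False)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2)


@dataclass(frozen=True)
class CounterfactualDataset:
    """Full counterfactual sample with columns (x, y0, y1, b), b = y1 − y0."""

    data: pd.DataFrame = field(repr=False)
    meta: dict = field(compare=False)

    def observed_view(self, seed: int) -> pd.DataFrame:
        """Randomized observed-data view: keep one arm's outcome per row."""
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 2, size=len(self.data))
        y = np.where(t == 1, self.data["y1"], self.data["y0"])
        return pd.DataFrame({"x": self.data["x"], "t": t, "y": y})

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2)


def sample_trial(pop: LogisticRCTPopulation, n: int, seed: int) -> TrialDataset:
    """i.i.d. draws from the logistic RCT: x ~ (a, b, 1−a−b), t ~ Bern(1/2) ⟂ x,
    y ~ Bern(Pr(Y=1 | t, x))."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    masses = pop.covariate_masses
    levels = np.array(sorted(masses))
    probs = np.array([masses[x] for x in levels])
    x = rng.choice(levels, size=n, p=probs / probs.sum())
    t = rng.integers(0, 2, size=n)
    p_y = np.array([outcome_prob(pop, ti, xi) for ti, xi in zip(t, x)])
    y = (rng.random(n) < p_y).astype(int)
    meta = {
        "population": {
            "a": pop.a,
            "b": pop.b,
            "beta_0": pop.beta_0,
            "beta_x": pop.beta_x,
            "beta_t": pop.beta_t,
            "beta_xt": pop.beta_xt,
        },
        "seed": seed,
        "n": n,
    }
    return TrialDataset(pd.DataFrame({"x": x, "t": t, "y": y}), meta)


def sample_counterfactual(
    model: GaussianCounterfactualModel, n: int, seed: int, dichotomize: bool = False
) -> CounterfactualDataset:
    """i.i.d. counterfactual draws: x ~ N(0, x_sd²), bivariate-normal noise with
    correlation ρ, y_t = α_t + β_t x + ε_t, optionally thresholded to {0, 1}."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if dichotomize and model.threshold is None:
        raise ValueError("dichotomize requires model.threshold")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, model.x_sd, size=n)
    cov = [
        [model.sigma0**2, model.rho * model.sigma0 * model.sigma1],
        [model.rho * model.sigma0 * model.sigma1, model.sigma1**2],
    ]
    eps = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    y0 = model.alpha0 + model.beta0 * x + eps[:, 0]
    y1 = model.alpha1 + model.beta1 * x + eps[:, 1]
    if dichotomize:
        y0 = (y0 > model.threshold).astype(int)
        y1 = (y1 > model.threshold).astype(int)
    df = pd.DataFrame({"x": x, "y0": y0, "y1": y1, "b": y1 - y0})
    meta = {
        "model": {k: getattr(model, k) for k in (
            "alpha0", "alpha1", "beta0", "beta1", "sigma0", "sigma1", "rho", "x_sd",
            "threshold",
        )},
        "seed": seed,
        "n": n,
        "dichotomize": dichotomize,
    }
    return CounterfactualDataset(df, meta)


def sample_matched_pairs(matched: MatchedPopulation, n: int, seed: int) -> pd.DataFrame:
    """i.i.d. matched-pair records (observed_benefit, predicted_benefit) drawn
    from the exact matched-population masses."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    masses = np.asarray(matched.masses)
    level = rng.choice(len(masses), size=n, p=masses / masses.sum())
    triples = np.stack([t.as_array() for t in matched.triples])  # (L, 3)
    u = rng.random(n)
    cum = triples.cumsum(axis=1)[level]  # (n, 3)
    benefit = (u[:, None] > cum).sum(axis=1) - 1  # −1, 0, +1
    h = np.asarray(matched.h_values, dtype=float)[level]
    return pd.DataFrame({"observed_benefit": benefit, "predicted_benefit": h})


def records_from_frame(df: pd.DataFrame) -> list[MatchedPairRecord]:
    """Convert a (observed_benefit, predicted_benefit) frame to records."""
    return [
        MatchedPairRecord(int(b), float(h))
        for b, h in zip(df["observed_benefit"], df["predicted_benefit"])
    ]
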