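"""Discrete treatment-benefit populations and exact pairwise order-relation tables.

A population here is a finite covariate distribution together with, for each
covariate level, the conditional distribution of the ternary individual
treatment benefit B = Y(1) − Y(0) ∈ {−1, 0, +1} (harm / no effect / benefit).
The best possible benefit predictor is the conditional mean h*(x) = E[B | X=x].

The central object for population-level concordance computations is the 3×3
table of joint probabilities of the order relations of the predictions and the
benefits of two independently drawn patients: rows index sign(H1 − H2), columns
index sign(B1 − B2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BENEFIT_LEVELS",
    "ProbabilityTriple",
    "DiscreteBenefitPopulation",
    "BenefitPredictor",
    "PairProbabilityTable",
    "true_predictor",
    "expected_benefit",
    "pair_table",
]

#: Ordered levels of the ternary benefit variable B.
BENEFIT_LEVELS = (-1, 0, 1)

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class ProbabilityTriple:
    """Distribution of ternary benefit B ∈ {−1, 0, +1} within one covariate stratum.

    Parameters
    ----------
    p_minus, p_zero, p_plus
        Probabilities of harm (B = −1), no effect (B = 0) and benefit (B = +1).
        Must be in [0, 1] and sum to 1 within 1e−12; invalid inputs are rejected
        rather than renormalized.
    """

    p_minus: float
    p_zero: float
    p_plus: float

    def __post_init__(self) -> None:
        vals = (self.p_minus, self.p_zero, self.p_plus)
        for v in vals:
            if not (-_PROB_TOL <= v <= 1 + _PROB_TOL):
                raise ValueError(f"probability component {v!r} outside [0, 1]")
        if abs(sum(vals) - 1.0) > _PROB_TOL:
            raise ValueError(f"probability triple {vals} does not sum to 1")

    def as_array(self) -> np.ndarray:
        """Probabilities ordered by benefit level (−1, 0, +1)."""
        return np.array([self.p_minus, self.p_zero, self.p_plus])

    @property
    def mean_benefit(self) -> float:
        """E[B] under this triple, i.e. p_plus − p_minus."""
        return self.p_plus - self.p_minus


class BenefitPredictor:
    """Deterministic treatment-benefit predictor h: covariate level → real prediction.

    Predictions are evaluated once per level and cached, so repeated lookups
    return bit-identical values and ties between levels are stable — ties carry
    half credit in the concordance statistic, so they are semantically
    meaningful and must not be split by float nondeterminism.
    """

    def __init__(self, values: Mapping[object, float]):
        self._values = {x: float(v) for x, v in values.items()}

    @classmethod
    def from_callable(
        cls, fn: Callable[[object], float], levels: Sequence[object]
    ) -> "BenefitPredictor":
        return cls({x: fn(x) for x in levels})

    def __call__(self, x: object) -> float:
        try:
            return self._values[x]
        except KeyError:
            raise KeyError(f"predictor undefined at covariate level {x!r}") from None

    def values_on(self, levels: Sequence[object]) -> np.ndarray:
        return np.array([self(x) for x in levels], dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BenefitPredictor({self._values!r})"


@dataclass(frozen=True)
class DiscreteBenefitPopulation:
    """Finite covariate distribution with a benefit triple per stratum.

    ``covariate_levels`` is an ordered finite set of covariate values;
    ``covariate_probs`` their probability masses (nonnegative, summing to 1);
    ``benefit_triples`` one :class:`ProbabilityTriple` per level.
    """

    covariate_levels: tuple
    covariate_probs: tuple
    benefit_triples: tuple

    def __init__(self, covariate_levels, covariate_probs, benefit_triples):
        levels = tuple(covariate_levels)
        probs = tuple(float(p) for p in covariate_probs)
        triples = tuple(
            t if isinstance(t, ProbabilityTriple) else ProbabilityTriple(*t)
            for t in benefit_triples
        )
        if len(set(levels)) != len(levels):
            raise ValueError("covariate levels must be distinct")
        if len(probs) != len(levels) or len(triples) != len(levels):
            raise ValueError("levels, probs and triples must have equal length")
        if any(p < -_PROB_TOL for p in probs):
            raise ValueError("covariate probabilities must be nonnegative")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ValueError("covariate probabilities must sum to 1")
        object.__setattr__(self, "covariate_levels", levels)
        object.__setattr__(self, "covariate_probs", probs)
        object.__setattr__(self, "benefit_triples", triples)

    @classmethod
    def from_dict(cls, spec: Mapping) -> "DiscreteBenefitPopulation":
        """Build from ``{"levels": [...], "probs": [...], "triples": [[p−,p0,p+], ...]}``."""
        return cls(spec["levels"], spec["probs"], spec["triples"])

    @classmethod
    def from_yaml(cls, path) -> "DiscreteBenefitPopulation":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "levels": list(self.covariate_levels),
            "probs": list(self.covariate_probs),
            "triples": [list(t.as_array()) for t in self.benefit_triples],
        }

    def triple_matrix(self) -> np.ndarray:
        """(n_levels, 3) array of Pr(B = level | X), columns ordered (−1, 0, +1)."""
        return np.stack([t.as_array() for t in self.benefit_triples])


_REL_LABELS = ("H1<H2", "H1=H2", "H1>H2")
_COL_LABELS = ("B1<B2", "B1=B2", "B1>B2")
_TABLE_TOL = 1e-10


@dataclass(frozen=True)
class PairProbabilityTable:
    """3×3 joint probabilities of the order relations of (H, B) for a random pair.

    Rows: (H1 < H2, H1 = H2, H1 > H2); columns: (B1 < B2, B1 = B2, B1 > B2).
    The draws are exchangeable, which forces the symmetries
    entry(H>, B>) = entry(H<, B<), entry(H>, B<) = entry(H<, B>),
    entry(H=, B>) = entry(H=, B<) and entry(H>, B=) = entry(H<, B=).
    """

    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError("pair table must be 3×3")
        if (arr < -_TABLE_TOL).any():
            raise ValueError("pair table entries must be nonnegative")
        if abs(arr.sum() - 1.0) > _TABLE_TOL:
            raise ValueError("pair table entries must sum to 1")
        # exchangeability: table must equal its 180° rotation
        if not np.allclose(arr, arr[::-1, ::-1], atol=_TABLE_TOL):
            raise ValueError("pair table violates exchangeability symmetry")
        object.__setattr__(self, "probs", arr)

    def cell(self, h_rel: str, b_rel: str) -> float:
        """Entry by relation label, e.g. ``cell(">", ">")`` or ``cell("=", ">")``."""
        order = {"<": 0, "=": 1, ">": 2}
        return float(self.probs[order[h_rel], order[b_rel]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(_REL_LABELS), columns=list(_COL_LABELS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PairProbabilityTable":
        return cls(pd.read_csv(path, index_col=0).to_numpy())


def true_predictor(pop: DiscreteBenefitPopulation) -> BenefitPredictor:
    """The conditional-mean benefit predictor h*(x) = E[B | X = x] = p₊(x) − p₋(x)."""
    return BenefitPredictor(
        {x: t.mean_benefit for x, t in zip(pop.covariate_levels, pop.benefit_triples)}
    )


def expected_benefit(pop: DiscreteBenefitPopulation) -> float:
    """Marginal mean benefit E[B] = Σ_x Pr(X=x) (p₊(x) − p₋(x))."""
    return float(
        sum(
            w * t.mean_benefit
            for w, t in zip(pop.covariate_probs, pop.benefit_triples)
        )
    )


def pair_table(pop: DiscreteBenefitPopulation, h: BenefitPredictor) -> PairProbabilityTable:
    """Exact pair-relation table for two independent draws from ``pop`` scored by ``h``.

    For every ordered pair of covariate levels (x1, x2) and benefit levels
    (b1, b2), the mass Pr(X=x1)Pr(X=x2)Pr(B=b1|x1)Pr(B=b2|x2) is accumulated
    into the cell indexed by (sign(h(x1) − h(x2)), sign(b1 − b2)).

    Raises ``KeyError`` if ``h`` is undefined on some covariate level.
    """
    w = np.asarray(pop.covariate_probs)
    P = pop.triple_matrix()  # (n, 3)
    hv = h.values_on(pop.covariate_levels)

    # joint mass over (x1, x2, b1, b2)
    joint = np.einsum("i,j,ia,jb->ijab", w, w, P, P)
    h_sign = np.sign(hv[:, None] - hv[None, :]).astype(int)  # (n, n)
    lv = np.array(BENEFIT_LEVELS)
    b_sign = np.sign(lv[:, None] - lv[None, :]).astype(int)  # (3, 3)

    table = np.zeros((3, 3))
    for r in (-1, 0, 1):
        hm = h_sign == r
        for c in (-1, 0, 1):
            bm = b_sign == c
            table[r + 1, c + 1] = joint[hm][:, bm].sum()
    return PairProbabilityTable(table)
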