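import numpy as np
import pytest
from hypothesis import settings

from cfbaudit import DiscreteBenefitPopulation, ProbabilityTriple

settings.register_profile("default", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("default")


def random_triple(rng: np.random.Generator) -> ProbabilityTriple:
    return ProbabilityTriple(*rng.dirichlet([1.0, 1.0, 1.0]))


def random_population(rng: np.random.Generator, n_levels: int | None = None) -> DiscreteBenefitPopulation:
    n = n_levels or int(rng.integers(2, 5))
    probs = rng.dirichlet(np.ones(n))
    triples = [random_triple(rng) for _ in range(n)]
    return DiscreteBenefitPopulation(tuple(range(n)), probs, triples)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230516)


@pytest.fixture
def worked_example():
    from cfbaudit import WORKED_EXAMPLE_POPULATION

    return WORKED_EXAMPLE_POPULATION
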