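import numpy as np
import pytest

from epoherit.pedigree import Pedigree, prune_informative
from epoherit.simulate import (
    PopulationSimConfig,
    TraitSimConfig,
    simulate_population_pedigree,
    simulate_trait,
)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_records([("child", "mum", "dad")])


@pytest.fixture
def full_sib_family() -> Pedigree:
    return Pedigree.from_records(
        [("a", "mum", "dad"), ("b", "mum", "dad"), ("inbred", "a", "b")],
        sex={"a": "F", "b": "M"},
    )


@pytest.fixture(scope="session")
def small_population():
    """A modest simulated population shared by the slower model tests:
    ~200 phenotyped breeders, pruned pedigree of a few hundred."""
    cfg = PopulationSimConfig(n_years=6, pairs_per_year=(100, 130), rng_seed=11)
    ped, skel = simulate_population_pedigree(cfg)
    pruned = prune_informative(ped, set(skel["individual"]))
    return pruned, skel


@pytest.fixture(scope="session")
def gaussian_dataset(small_population):
    pruned, skel = small_population
    cfg = TraitSimConfig(
        sigma2_A=0.4, sigma2_R=0.6, family="gaussian-identity",
        intercept_mu=0.0, rng_seed=2,
    )
    return pruned, simulate_trait(pruned, skel, cfg)


@pytest.fixture(scope="session")
def poisson_dataset(small_population):
    pruned, skel = small_population
    cfg = TraitSimConfig(sigma2_A=0.5, sigma2_R=1.0, rng_seed=7)
    return pruned, simulate_trait(pruned, skel, cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
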