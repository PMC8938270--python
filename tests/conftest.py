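import numpy as np
import pytest

from wgr.core import DAY5, NOISELESS
from wgr.embryo_reconstruction import reconstruct_embryo
from wgr.synthetic_cohort import SyntheticFamily, simulate_family


@pytest.fixture(scope="session")
def day5_family() -> SyntheticFamily:
    """Six sibling embryos at day-5 noise, half the sites on the array."""
    return simulate_family(
        n_embryos=6, noise=DAY5, seed=11, n_sites=2000, n_chromosomes=2,
        n_array_sites=1000,
    )


@pytest.fixture(scope="session")
def noiseless_family() -> SyntheticFamily:
    """Four embryos, zero noise, fully observed array (every analysis site on
    the manifest), so reconstruction is exact in principle."""
    return simulate_family(
        n_embryos=4, noise=NOISELESS, seed=5, n_sites=1500, n_chromosomes=2,
        n_array_sites=1500,
    )


def reconstruct_all(family: SyntheticFamily, profile=None):
    """Reconstruct every embryo of a synthetic family against the truth-phased
    parents; returns (genomes, paths)."""
    profile = profile or family.noise
    genomes, paths = [], []
    for e in family.embryos:
        g, p = reconstruct_embryo(
            e.observation, family.mother, family.father, family.genetic_map, profile
        )
        genomes.append(g)
        paths.append(p)
    return genomes, paths


@pytest.fixture(scope="session")
def day5_reconstructions(day5_family):
    return reconstruct_all(day5_family)


@pytest.fixture(scope="session")
def noiseless_reconstructions(noiseless_family):
    return reconstruct_all(noiseless_family)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
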