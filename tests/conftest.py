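import numpy as np
import pytest

from sdlmap import GeneticMap, SimConfig, simulate_selected_population
from sdlmap.genome_map import Marker
from sdlmap.liability import CofactorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_map():
    """Two short chromosomes with uneven spacing."""
    return GeneticMap(
        {
            "1": [Marker("m1", 0.0), Marker("m2", 5.0), Marker("m3", 12.0)],
            "2": [Marker("m4", 0.0), Marker("m5", 8.0)],
        }
    )


@pytest.fixture(scope="session")
def small_selected():
    """A small selected population with one strong locus and a sex effect."""
    cfg = SimConfig(
        n_chromosomes=1,
        length_cM=200.0,
        spacing_cM=5.0,
        effects=[(50.0, 1.4135, 0.0)],
        cofactors=[CofactorSpec("sex", "discrete", beta=1.0)],
        n_survivors=300,
        seed=11,
    )
    return simulate_selected_population(cfg)


def enumerate_multipoint(positions, observed, prior, query=None):
    """Brute-force multipoint genotype probabilities by path enumeration.

    ``observed`` is a list of length m with entries None (missing) or a
    genotype class in {0, 1, 2}.  Returns an (m, 3) array of conditional
    probabilities, summing over all 3^m genotype paths.
    """
    from itertools import product

    from sdlmap.genome_map import f2_transition_matrix, recomb_fraction

    m = len(positions)
    trans = [
        f2_transition_matrix(recomb_fraction(b - a))
        for a, b in zip(positions, positions[1:])
    ]
    post = np.zeros((m, 3))
    total = 0.0
    for path in product(range(3), repeat=m):
        if any(o is not None and g != o for g, o in zip(path, observed)):
            continue
        p = prior[path[0]]
        for j in range(1, m):
            p *= trans[j - 1][path[j - 1], path[j]]
        total += p
        for j, g in enumerate(path):
            post[j, g] += p
    return post / total
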