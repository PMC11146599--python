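"""Shared fixtures: small seeded simulations reused across test modules.

The quad simulation follows the standard recovery benchmark: four tips on
a balanced tree, 11 chromosomes x 100 kbp, with 2 inversions (5-10 kbp),
5 translocations (1-3 kbp) and 8 duplications (0.5-2 kbp) planted per
branch at 0.5%/unit substitution rate.  Classifying all six pairs takes a
minute or two, so it is built once per session.
"""

import itertools

import pytest

from syntevo.classification import classify_pair
from syntevo.simulate import (
    EvolutionRates, SimulationConfig, SizeDist, simulate_clade, tree_from_string,
)

QUAD_NEWICK = "((A:0.01,B:0.01):0.02,(C:0.01,D:0.01):0.02);"
QUAD_SEED = 1


def quad_rates() -> EvolutionRates:
    return EvolutionRates(
        substitution_rate=0.005,
        small_indel_rate=0.0,
        insertion_rate=0.0,
        deletion_rate=0.0,
        inversion_size=SizeDist("uniform", 5000, 10000),
        translocation_size=SizeDist("uniform", 1000, 3000),
        duplication_size=SizeDist("uniform", 500, 2000),
    ).with_fixed_counts(INV=2, TRANS=5, DUP=8)


@pytest.fixture(scope="session")
def quad_sim():
    tree = tree_from_string(QUAD_NEWICK)
    config = SimulationConfig(n_chromosomes=11, chromosome_length=100_000, seed=QUAD_SEED)
    return simulate_clade(tree, config, quad_rates(), seed=QUAD_SEED)


@pytest.fixture(scope="session")
def quad_pairs(quad_sim):
    pairs = {}
    for x, y in itertools.combinations(sorted(quad_sim.tip_genomes), 2):
        pairs[(x, y)] = classify_pair(
            quad_sim.tip_genomes[x], quad_sim.tip_genomes[y], ref_id=x, qry_id=y
        )
    return pairs


CATERPILLAR_NEWICK = "(((((A:0.05,B:0.05):0.05,C:0.1):0.1,D:0.2):0.2,E:0.4):0.1,F:0.5);"
CATERPILLAR_SEED = 9


@pytest.fixture(scope="session")
def caterpillar_sim():
    """6-tip caterpillar whose pairwise path lengths span a 10x range,
    evolved under the default mutation regime."""
    tree = tree_from_string(CATERPILLAR_NEWICK)
    config = SimulationConfig(n_chromosomes=4, chromosome_length=50_000, seed=CATERPILLAR_SEED)
    return simulate_clade(tree, config, EvolutionRates(), seed=CATERPILLAR_SEED)


@pytest.fixture(scope="session")
def caterpillar_pairs(caterpillar_sim):
    pairs = {}
    for x, y in itertools.combinations(sorted(caterpillar_sim.tip_genomes), 2):
        pairs[(x, y)] = classify_pair(
            caterpillar_sim.tip_genomes[x], caterpillar_sim.tip_genomes[y],
            ref_id=x, qry_id=y,
        )
    return pairs
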