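import numpy as np
import pytest

from mapforge.model import GenotypeMatrix
from mapforge.synthetic_data import (
    corrupt_assembly,
    default_genome,
    genome_placement,
    simulate_population,
    true_partition,
    truth_linkage_map,
)


@pytest.fixture(scope="session")
def small_genome():
    """3 chromosomes x 60 markers: enough structure for every stage."""
    return default_genome(n_chromosomes=3, markers_per_chromosome=60)


@pytest.fixture(scope="session")
def small_population(small_genome):
    return simulate_population(small_genome, n_lines=300, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return corrupt_assembly(
        genome_placement(small_genome),
        n_inversions=2,
        n_translocations=1,
        n_detached_scaffolds=2,
        seed=9,
        partition=true_partition(small_genome),
    )


@pytest.fixture(scope="session")
def small_truth_map(small_genome):
    return truth_linkage_map(small_genome)


def random_genotypes(rng: np.random.Generator, n_markers: int, n_lines: int,
                     population_id: str = "RAND") -> GenotypeMatrix:
    calls = rng.integers(0, 4, size=(n_markers, n_lines)).astype(np.int8)
    return GenotypeMatrix(
        population_id,
        [f"L{i}" for i in range(n_lines)],
        [f"m{i}" for i in range(n_markers)],
        calls,
    )
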