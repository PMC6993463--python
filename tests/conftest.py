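import numpy as np
import pytest

from repeatpop import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def three_family_specs():
    return [
        sim.RepeatFamilySpec("famA", "Gypsy-like", 600, 45, 0.05, 0.0),
        sim.RepeatFamilySpec("famB", "Copia-like", 500, 50, 0.05, 0.0),
        sim.RepeatFamilySpec("famC", "tandem", 180, 140, 0.05, 0.0),
    ]


@pytest.fixture(scope="session")
def small_genome(three_family_specs):
    library = sim.make_repeat_library(three_family_specs, 1)
    genome = sim.build_genome(
        library, None, {"chr1": 100_000}, 1, n_genes_per_chrom=10
    )
    return library, genome


@pytest.fixture(scope="session")
def small_reads(small_genome):
    _, genome = small_genome
    return sim.shotgun_reads(genome, 400, 150, 2, individual="i1", population="SS")


def make_poisson_genome(n_families: int, copies_per_family: int) -> sim.SyntheticGenome:
    """Placeholder genome whose truth table fixes per-family mean copy numbers."""
    placements = [
        sim.Placement(f"fam{i:03d}", "chr1", 0, 1, "+")
        for i in range(n_families)
        for _ in range(copies_per_family)
    ]
    return sim.SyntheticGenome(chromosomes={"chr1": "ACGT"}, genes=[], truth_placements=placements)
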