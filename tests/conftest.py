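import numpy as np
import pytest

from plastidkit.simulate import SyntheticSpec, gen_genome, gen_species_set


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Desk-scale study conditions: ~36 kb genome, 20 genes."""
    return SyntheticSpec(
        seed=11,
        n_genes=20,
        codons_per_gene=120,
        region_lengths=(20_000, 6_000, 4_000),
        n_hotspots=3,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return gen_genome(small_spec)


@pytest.fixture(scope="session")
def species_set(small_spec):
    """Five synthetic species genomes plus their (indel-free) alignment."""
    return gen_species_set(small_spec, n_taxa=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_count_table(rng: np.random.Generator, n_codons: int = 2000):
    """A random codon count table (helper shared by several test modules)."""
    from plastidkit._genetics import ALL_CODONS

    weights = rng.dirichlet(np.ones(64))
    draws = rng.multinomial(n_codons, weights)
    return dict(zip(ALL_CODONS, (int(x) for x in draws)))
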