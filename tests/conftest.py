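import numpy as np
import pytest

from rangeedge import GenotypeMatrix, SplitModelConfig, simulate_split_genotypes


def make_matrix(geno, pops=None, locus_per_site=None, locus_length=51, n_loci=None):
    """Small helper to build a GenotypeMatrix from a plain array."""
    geno = np.asarray(geno, dtype=np.int8)
    n_ind, n_sites = geno.shape
    if pops is None:
        pops = ["pop1"] * n_ind
    if locus_per_site is None:
        locus_per_site = [f"locus{i:04d}" for i in range(n_sites)]
    return GenotypeMatrix(
        geno,
        [f"s{i:02d}" for i in range(n_ind)],
        np.array(pops, dtype=object),
        np.array(locus_per_site, dtype=object),
        np.ones(n_sites, dtype=int),
        locus_length=locus_length,
        n_loci_assayed=n_loci,
    )


@pytest.fixture(scope="session")
def default_split_dataset():
    """The default 5-deme synthetic RADseq dataset (shared across tests)."""
    return simulate_split_genotypes(SplitModelConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
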