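import numpy as np
import pytest

from hierstruct import GenotypeMatrix


@pytest.fixture
def tiny_matrix():
    """2 populations x 2 individuals each, 2 loci, no missing data."""
    alleles = np.array(
        [
            [[150, 152], [7, 7]],
            [[150, 150], [7, 9]],
            [[152, 152], [9, 9]],
            [[150, 152], [9, 9]],
        ]
    )
    return GenotypeMatrix(
        individual_ids=["a1", "a2", "b1", "b2"],
        pop_labels=["Pop1", "Pop1", "Pop2", "Pop2"],
        alleles=alleles,
        locus_names=["L1", "L2"],
    )


def random_matrix(rng, n_ind=20, n_loci=12, n_pops=2, max_allele=99, missing_rate=0.0):
    """Random valid matrix with allele codes in 1..max_allele."""
    alleles = rng.integers(1, max_allele + 1, size=(n_ind, n_loci, 2))
    if missing_rate:
        alleles[rng.random(alleles.shape) < missing_rate] = -1
    pops = [f"Pop{1 + (i * n_pops) // n_ind}" for i in range(n_ind)]
    return GenotypeMatrix(
        individual_ids=[f"ind{i}" for i in range(n_ind)],
        pop_labels=pops,
        alleles=alleles,
        locus_names=[f"L{j}" for j in range(n_loci)],
    )
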