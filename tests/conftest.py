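import numpy as np
import pytest

from island_popgen.genotype_io import GenotypeMatrix


@pytest.fixture
def three_pop_matrix() -> GenotypeMatrix:
    """Handcrafted 3 populations x 2 loci with one missing genotype."""
    alleles = np.array(
        [
            # popA
            [[100, 102], [100, 100]],
            [[100, 100], [102, 104]],
            [[100, 102], [0, 0]],
            # popB
            [[102, 102], [100, 100]],
            [[102, 104], [100, 102]],
            # popC
            [[104, 104], [104, 104]],
            [[104, 104], [104, 102]],
        ],
        dtype=np.int64,
    )
    return GenotypeMatrix(
        [f"i{k}" for k in range(7)],
        ["locA", "locB"],
        alleles,
        ["popA"] * 3 + ["popB"] * 2 + ["popC"] * 2,
    )


def random_matrix(
    rng: np.random.Generator,
    n_pops: int = 3,
    n_per_pop: int = 8,
    n_loci: int = 2,
    n_alleles: int = 4,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Random diploid fixture with optional locus-wise missingness."""
    n = n_pops * n_per_pop
    alleles = rng.integers(10, 10 + n_alleles, size=(n, n_loci, 2))
    if missing_rate:
        mask = rng.random((n, n_loci)) < missing_rate
        alleles[mask] = 0
    return GenotypeMatrix(
        [f"ind{k}" for k in range(n)],
        [f"L{j}" for j in range(n_loci)],
        alleles,
        [f"pop{p}" for p in range(n_pops) for _ in range(n_per_pop)],
    )
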