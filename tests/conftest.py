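import numpy as np
import pytest

from admixkit.genotype_io import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genotypes(rng, I, J, missing_frac=0.0) -> GenotypeMatrix:
    counts = rng.integers(0, 3, size=(I, J)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random((I, J)) < missing_frac
        counts[mask] = -1
    return GenotypeMatrix(
        counts,
        [f"ind{i}" for i in range(I)],
        [f"snp{j}" for j in range(J)],
    )


@pytest.fixture
def small_genotypes(rng):
    return random_genotypes(rng, 8, 12, missing_frac=0.1)
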