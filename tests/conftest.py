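import numpy as np
import pytest

from stepcmh import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20150925)


def random_table(rng, shape=(2, 3), low=0, high=10, min_total=2):
    """Random count slice with non-degenerate margins."""
    while True:
        t = rng.integers(low, high, size=shape)
        if (
            t.sum() >= min_total
            and (t.sum(axis=1) > 0).all()
            and (t.sum(axis=0) > 0).all()
        ):
            return t


def make_genotypes(codes, snp_ids=None, sample_ids=None):
    codes = np.asarray(codes)
    n, p = codes.shape
    return GenotypeMatrix(
        codes,
        snp_ids or [f"rs{j + 1}" for j in range(p)],
        sample_ids or [f"s{i + 1}" for i in range(n)],
    )
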