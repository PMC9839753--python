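import numpy as np
import pytest

import latentdomains as ld


@pytest.fixture(scope="session")
def planted_4factor():
    """40 variables in 4 blocks, loadings 0.6-0.8, n = 600 subjects."""
    rng = np.random.default_rng(42)
    L = ld.block_loadings(4, 10, 0.7, rng=rng, jitter=0.1)  # in [0.6, 0.8]
    spec = ld.SyntheticSpec(
        n_subjects=600,
        loadings=L,
        uniquenesses=1.0 - (L**2).sum(axis=1),
        seed=42,
    )
    table, truth = ld.generate_factor_data(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def planted_3block():
    """30 variables in 3 blocks with within-block correlation 0.9."""
    loading = np.sqrt(0.9)
    L = ld.block_loadings(3, 10, loading)
    spec = ld.SyntheticSpec(
        n_subjects=300,
        loadings=L,
        uniquenesses=1.0 - (L**2).sum(axis=1),
        seed=7,
    )
    table, truth = ld.generate_factor_data(spec)
    return spec, table, truth


def set_partitions(n):
    """All partitions of range(n) as label arrays (restricted-growth strings)."""
    def rec(prefix, maxlab):
        if len(prefix) == n:
            yield np.array(prefix)
            return
        for lab in range(maxlab + 2):
            yield from rec(prefix + [lab], max(maxlab, lab))

    yield from rec([0], 0)
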