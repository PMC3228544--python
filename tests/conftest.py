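import numpy as np
import pytest

from ridgesig import build_coalescent_panel, build_haplotype_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def copying_panel():
    """Small copying-model panel for simulator unit tests."""
    return build_haplotype_panel(H=4000, M=300, seed=101)


@pytest.fixture(scope="session")
def small_coalescent_panel():
    """Small coalescent panel (fast) for simulator and end-to-end tests."""
    return build_coalescent_panel(n_haplotypes=2000, sequence_length=2e5, seed=202)


@pytest.fixture(scope="session")
def study_panel():
    """Full-size study panel: 21,000 haplotypes over 1 Mb (built once)."""
    return build_coalescent_panel(seed=777)


@pytest.fixture
def tall_design(rng):
    """n > m full-rank design with a correlated response."""
    n, m = 40, 5
    X = rng.standard_normal((n, m))
    beta = np.array([1.0, -0.5, 0.0, 0.25, 2.0])
    y = X @ beta + rng.standard_normal(n)
    return X, y


@pytest.fixture
def wide_design(rng):
    """m > n design (ridge-only regime)."""
    n, m = 12, 30
    X = rng.standard_normal((n, m))
    y = X[:, 0] - X[:, 5] + rng.standard_normal(n)
    return X, y
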