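import numpy as np
import pytest

import kernelgxe as kg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def std_markers():
    """Standardized 40 x 200 marker matrix."""
    raw = kg.simulate_markers(40, 200, (0.1, 0.5), seed=11)
    X, _ = kg.standardize_markers(raw, maf_threshold=0.0, seed=11)
    return X


@pytest.fixture
def linear_K(std_markers):
    return kg.linear_kernel(std_markers)


@pytest.fixture
def toy_table(rng):
    """30 lines x 3 environments, fully observed."""
    n, m = 30, 3
    vals = rng.standard_normal((n, m))
    return kg.PhenotypeTable([f"L{i}" for i in range(n)],
                             [f"E{j}" for j in range(m)], vals)


def make_identity_kernel(n):
    return kg.KernelMatrix([f"L{i}" for i in range(n)], np.eye(n), kind="custom")
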