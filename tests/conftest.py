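import numpy as np
import pytest

from audimpute.synthetic import GeneratorParams, generate_dense, generate_sparse


@pytest.fixture(scope="session")
def registry_parent():
    """Large sparse parent emulating a pooled CI-candidate audiogram registry.

    Sized so that per-fold complete-case subsets reach the sample range where
    regression-based imputers plateau (~900 dense training rows at 3 outer
    folds).
    """
    return generate_sparse(GeneratorParams(n=70000, seed=11))


@pytest.fixture(scope="session")
def dense_pool():
    """Fully observed synthetic audiograms for amputation-based tests."""
    return generate_dense(GeneratorParams(n=500, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
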