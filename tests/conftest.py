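import numpy as np
import pytest

from grngpea.io_formats import ExpressionMatrix
from grngpea import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng) -> ExpressionMatrix:
    """8 independent Gaussian genes x 40 samples."""
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(8)],
        sample_ids=[f"s{j}" for j in range(40)],
        values=rng.standard_normal((8, 40)),
    )


@pytest.fixture(scope="session")
def small_bundle() -> synthetic.SyntheticBundle:
    """Small planted study shared by read-only tests."""
    return synthetic.make_bundle(p=120, n=100, seed=7)
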