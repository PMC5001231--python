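import numpy as np
import pytest

from ccindex import ExpressionMatrix, make_correlated_matrix, make_two_condition_study

# planted two-condition study builder, shared across test modules
make_two_condition_data = make_two_condition_study


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def correlated_50x100(rng):
    """Noiseless perfectly co-expressed module at the standard size."""
    return make_correlated_matrix(50, 100, rng)


@pytest.fixture
def noise_genome(rng):
    """400 mutually uncorrelated genes over 60 samples."""
    values = rng.normal(size=(400, 60))
    return ExpressionMatrix(
        values,
        [f"g{i:04d}" for i in range(400)],
        [f"s{j:03d}" for j in range(60)],
    )
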