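import numpy as np
import pytest

from tphpmf.preprocessing import CountMatrix, log_transform, normalize_counts


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    values = rng.poisson(50, size=(6, 8)).astype(float)
    values[0, 0] = 0.0
    values[3, 5] = 0.0
    return CountMatrix(
        values,
        [f"s{i}" for i in range(6)],
        [f"t{j}" for j in range(8)],
    )


@pytest.fixture
def small_log(small_counts):
    return log_transform(normalize_counts(small_counts))
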