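import numpy as np
import pytest

from metamiss import IntensityMatrix


@pytest.fixture
def small_matrix() -> IntensityMatrix:
    """3x2 table with one missing cell."""
    values = np.array([[1.0, 10.0], [2.0, np.nan], [3.0, 30.0]])
    mask = np.isnan(values)
    return IntensityMatrix(values, mask, ["s1", "s2", "s3"], ["m1", "m2"])


@pytest.fixture
def complete_matrix() -> IntensityMatrix:
    rng = np.random.default_rng(7)
    values = np.exp(rng.normal(5.0, 1.0, size=(8, 5)))
    return IntensityMatrix(values, np.zeros_like(values, dtype=bool))


def random_masked_matrix(seed: int, n: int = 10, m: int = 6, frac: float = 0.2) -> IntensityMatrix:
    """Random positive matrix with an MCAR-ish mask keeping >=2 observations
    per column."""
    rng = np.random.default_rng(seed)
    values = np.exp(rng.normal(3.0, 1.0, size=(n, m)))
    mask = rng.random((n, m)) < frac
    for j in range(m):
        obs = np.nonzero(~mask[:, j])[0]
        if obs.size < 2:
            mask[rng.choice(n, size=2, replace=False), j] = False
    return IntensityMatrix(values, mask)
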