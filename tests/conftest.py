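import numpy as np
import pytest

from mstraj.cohort import EDSS_LADDER, EDSSSeries, ladder_value, series_from_pairs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240716)


def random_ladder_walk(rng, length=None, min_len=2, max_len=40) -> EDSSSeries:
    """A random on-ladder series with irregular visit days."""
    n = int(length or rng.integers(min_len, max_len + 1))
    days = np.cumsum(rng.integers(1, 400, size=n)).astype(float)
    days -= days[0]
    idx = rng.integers(0, 20)
    indices = [idx]
    for _ in range(n - 1):
        idx = int(np.clip(idx + rng.integers(-2, 3), 0, 19))
        indices.append(idx)
    return EDSSSeries(tuple(days), tuple(ladder_value(i) for i in indices))


@pytest.fixture
def constant_series():
    return series_from_pairs([(0, 2.0), (400, 2.0), (900, 2.0)])


assert len(EDSS_LADDER) == 20
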