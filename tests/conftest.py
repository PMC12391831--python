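import numpy as np
import pytest
from hypothesis import settings

from ghostforest import RingWidthSeries, SeriesSet

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def constant_series():
    return RingWidthSeries("CONST", 1900, np.full(60, 1.2))


@pytest.fixture
def negexp_series():
    """Noiseless widths from a known negative-exponential age trend."""
    t = np.arange(100, dtype=float)
    return RingWidthSeries("NEGEXP", 1900, 2.0 * np.exp(-0.05 * t) + 0.5)


@pytest.fixture
def toy_series_set():
    rng = np.random.default_rng(7)
    series = [
        RingWidthSeries(f"T{i:02d}", 1950, np.exp(rng.normal(0, 0.2, 50)), tree_id=f"T{i:02d}")
        for i in range(4)
    ]
    return SeriesSet("TOY", series)
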