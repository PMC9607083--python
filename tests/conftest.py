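import numpy as np
import pytest

from lagtox import SynthConfig, simulate_all
from lagtox.panel import SeriesId, WeeklySeries, weekly_index


@pytest.fixture(scope="session")
def idx312():
    """A 312-week index starting on the default Monday anchor."""
    return weekly_index("2015-01-05", "2020-12-28")[:312]


@pytest.fixture(scope="session")
def default_sim():
    """One full generator run with default study conditions (cached)."""
    cfg = SynthConfig(seed=42)
    return cfg, simulate_all(cfg)


@pytest.fixture
def make_series(idx312):
    def _make(values, area="A", variable="v", species=None, index=None):
        idx = index if index is not None else idx312[: len(values)]
        return WeeklySeries(SeriesId(area, variable, species), idx,
                            np.asarray(values, dtype=float))

    return _make
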