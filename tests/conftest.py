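import numpy as np
import pytest

from dhxflex.fragments import ResidueExchangeCurve
from dhxflex.simulate import DEFAULT_TIME_GRID


@pytest.fixture
def time_grid():
    return DEFAULT_TIME_GRID.copy()


def make_curve(times, values, sigma=0.01, position=5):
    """Residue exchange curve helper for fitting tests."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    return ResidueExchangeCurve(
        position=position,
        times=times,
        d_mean=values,
        d_sigma=np.full(times.size, sigma),
        n_fragments_used=np.full(times.size, 2, dtype=int),
    )
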