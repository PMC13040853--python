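import numpy as np
import pytest

from exengage.sced_stats import ATDSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alternating_series(n_comparisons: int, n_favourable: int,
                            favoured: str = "feedback") -> ATDSeries:
    """Strictly alternating series engineered to win exactly
    ``n_favourable`` of ``n_comparisons`` adjacent comparisons."""
    other = "no_feedback" if favoured == "feedback" else "feedback"
    conds, vals = [], []
    for i in range(n_comparisons):
        conds += [favoured, other]
        vals += ([1.0, 0.5] if i < n_favourable else [0.5, 1.0])
    return ATDSeries.from_values(conds, vals)


@pytest.fixture
def alternating_series():
    return make_alternating_series
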