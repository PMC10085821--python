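import numpy as np
import pandas as pd
import pytest

from tagrecover.preprocess import DIVE_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dive_table(rows):
    """rows: (animal_id, start_h, duration_s, category)."""
    return pd.DataFrame(
        [(a, s, d, np.nan, c) for a, s, d, c in rows], columns=DIVE_COLUMNS
    )


@pytest.fixture
def dive_table_factory():
    return make_dive_table
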