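import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from diurnality.io import HourlySeries

settings.register_profile("repro", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("repro")


def make_series(values, start="2018-01-01", term="pink eye", location="NY",
                replicate=1, tz="UTC", **kwargs):
    """Small HourlySeries builder used across test modules."""
    values = np.asarray(values, dtype=float)
    index = pd.date_range(start, periods=len(values), freq="h", tz=tz)
    frame = pd.DataFrame({"rsv": values}, index=index)
    return HourlySeries(term=term, location=location, replicate=replicate,
                        frame=frame, **kwargs)


@pytest.fixture
def small_series():
    rng = np.random.default_rng(42)
    return make_series(np.clip(50 + rng.normal(0, 5, 72), 0, 100))
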