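import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from fragmap import Epoch


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_epoch():
    """3 electrodes x 100 samples at 100 Hz starting 1 s before onset."""
    rs = np.random.default_rng(7)
    data = rs.standard_normal((3, 100)) * 50.0
    return Epoch(
        data=data,
        electrodes=["LA1", "LA2", "LB1"],
        start_time=-1.0,
        sampling_rate=100.0,
        row_data=pd.DataFrame({"soz": [True, False, False],
                               "resected": [True, True, False]}),
        meta_data={"patient": "synthetic-test", "outcome": "n/a"},
    )


def random_epoch(rs: np.random.Generator, m=None, n=None) -> Epoch:
    """Random epoch for property tests."""
    m = m or int(rs.integers(2, 7))
    n = n or int(rs.integers(10, 200))
    return Epoch(
        data=rs.standard_normal((m, n)) * 100,
        electrodes=[f"C{i}" for i in range(m)],
        start_time=float(rs.uniform(-5, 5)),
        sampling_rate=float(rs.choice([100.0, 250.0, 500.0, 1000.0])),
        row_data=pd.DataFrame({"soz": rs.random(m) < 0.3}),
        meta_data={"sex": "F", "nested": {"a": [1, 2]}},
    )
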