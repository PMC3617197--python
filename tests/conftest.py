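import numpy as np
import pandas as pd
import pytest

import dualrace as dr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def basic_params():
    """A mid-range hybrid parameter set used across unit tests."""
    return dr.HybridParams(
        theta=500.0, mu_int=1.4, sigma_int=1.2, mu_ext=1.1, sigma_ext=0.4,
        exec_delay=125.0, accel=40.0,
    )


def make_designs(rng, n, bias=None, gap_range=(0.0, 330.0)):
    gaps = rng.uniform(*gap_range, size=n)
    if bias is None:
        target = np.where(rng.uniform(size=n) < 0.5, "L", "R")
        mfs = np.full(n, None, dtype=object)
    else:
        mfs = np.where(rng.uniform(size=n) < 0.5, "L", "R").astype(object)
        other = np.where(mfs == "L", "R", "L")
        target = np.where(rng.uniform(size=n) < bias, mfs, other)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "gap_ms": gaps,
            "target_side": target.astype("U1"),
            "more_frequent_side": mfs,
        }
    )


@pytest.fixture
def designs_factory():
    return make_designs
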