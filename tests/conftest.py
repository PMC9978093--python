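import numpy as np
import pandas as pd
import pytest

import gazefeit as gf


@pytest.fixture(scope="session")
def adult_profiles():
    return gf.default_profiles("adult")


@pytest.fixture(scope="session")
def small_cohort(adult_profiles):
    """2 control + 2 ASD adults, full 21-trial banks."""
    cfg = gf.CohortConfig(
        groups=[(adult_profiles["control"], 2), (adult_profiles["ASD"], 2)],
        population="adult",
        seed=11,
    )
    return gf.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return gf.cohort_features(small_cohort)


def make_gaze(points, valid=None, rate_hz=120.0):
    """Gaze table from an (n, 2) point array; both eyes at the same point."""
    points = np.asarray(points, float)
    n = len(points)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    return pd.DataFrame(
        {
            "t_ms": np.arange(n) / rate_hz * 1000.0,
            "lx": np.where(valid, points[:, 0], np.nan),
            "ly": np.where(valid, points[:, 1], np.nan),
            "rx": np.where(valid, points[:, 0], np.nan),
            "ry": np.where(valid, points[:, 1], np.nan),
            "lvalid": valid,
            "rvalid": valid,
        }
    )
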