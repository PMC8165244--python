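import numpy as np
import pandas as pd
import pytest

from facepulse.pulse_extraction import RRSeries
from facepulse import synthetic_cohort as sc


def rr_from_list(values_ms, t0=0.0):
    """RRSeries from a plain list of intervals (ms), cumulative timing."""
    values = np.asarray(values_ms, dtype=float)
    t = t0 + np.cumsum(values) / 1000.0
    return RRSeries(intervals=values, t=t)


@pytest.fixture
def rr_800():
    """Five-minute constant 800 ms series."""
    return rr_from_list([800.0] * 375)


@pytest.fixture
def tiny_cohort_config():
    """Small, fast cohort: 4+4 participants, 60 s clips."""
    return sc.CohortConfig(
        n_td=4,
        n_asd=4,
        clip_durations={c: 60.0 for c in sc.CLIP_NAMES},
        master_seed=11,
    )


@pytest.fixture
def random_feature_table():
    """Null 12-participant feature table with the real 120 columns."""
    from facepulse.feature_pipeline import FEATURE_NAMES

    rng = np.random.default_rng(7)
    table = pd.DataFrame(
        rng.normal(size=(12, len(FEATURE_NAMES))),
        columns=list(FEATURE_NAMES),
        index=[f"P{i:02d}" for i in range(12)],
    )
    table.insert(0, "group", ["TD"] * 6 + ["ASD"] * 6)
    table.index.name = "participant"
    return table
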