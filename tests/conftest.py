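import numpy as np
import pytest

import dcipred as dp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cohort():
    """Small dense synthetic cohort on a coarse grid (fast unit-test input)."""
    cs = dp.CohortSpec(n=12, prevalence=0.4, period_s=300.0, span_days=4.0,
                       gap_rate_per_day=1.0, mean_gap_minutes=30.0,
                       missing_channel_prob=0.0, seed=7)
    return dp.generate_cohort(cs, dp.MotifSpec(amplitude=5.0))


def series(values, period=60.0, start=0.0):
    return dp.TimeSeries(np.asarray(values, float), period, start)
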