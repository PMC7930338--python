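import numpy as np
import pytest

import regularogram as rg

COHORT_SEED = 2021


@pytest.fixture(scope="session")
def mixed_cohort():
    """20 paroxysmal records with minority regularly-irregular runs."""
    return rg.gen_cohort(20, (0.05, 0.95), seed=COHORT_SEED, other_rhythms=True)


@pytest.fixture(scope="session")
def mixed_cohort_indices(mixed_cohort):
    return [rg.compute_indices(rec.rr, rec.segments) for rec in mixed_cohort]


@pytest.fixture(scope="session")
def paroxysmal_record():
    """One NSR / AF / NSR record with a known mid-record rhythm switch."""
    return rg.gen_record([(rg.NSR_PROFILE, 1200), (rg.AF_PROFILE, 600),
                          (rg.NSR_PROFILE, 1200)], seed=11)


@pytest.fixture()
def rr_series():
    def make(values, record_id="test"):
        values = np.asarray(values, dtype=float)
        return rg.RRSeries(intervals=values, timestamps=np.cumsum(values),
                           record_id=record_id)
    return make
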