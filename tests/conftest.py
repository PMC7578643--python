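import pandas as pd
import pytest

import sepsisdtr as s


@pytest.fixture(scope="session")
def params():
    return s.default_params()


@pytest.fixture(scope="session")
def cohort_small(params):
    """Small simulated cohort shared by read-only tests."""
    return s.simulate_frame(params, 400, seed=7)


@pytest.fixture(scope="session")
def wide_small(cohort_small):
    return s.cohort_to_wide(cohort_small)


@pytest.fixture(scope="session")
def fitted_small(cohort_small):
    return s.DynamicRegimeEstimator().fit(cohort_small)


@pytest.fixture(scope="session")
def published():
    return s.published_rules()


def make_trajectory(pid="p1", age=60.0, icu="MICU", n_days=5, death=None,
                    discharge=None, fluid=20.0, **daily):
    """Hand-built trajectory with constant daily values."""
    recs = [s.DailyRecord(day=d, hr=daily.get("hr", 100.0),
                          mbp=daily.get("mbp", 60.0), rr=daily.get("rr", 25.0),
                          temp=daily.get("temp", 37.0),
                          urine_ml=daily.get("urine_ml", 800.0),
                          mv=daily.get("mv", 0), vasopressor=daily.get("vaso", 0),
                          fluid_ml_per_kg=fluid if not isinstance(fluid, dict)
                          else fluid.get(d, 20.0))
            for d in range(1, n_days + 1)]
    return s.Trajectory(patient_id=pid, age=age, icu_type=icu,
                        daily_records=recs, death_time=death,
                        discharge_time=discharge)
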