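import numpy as np
import pytest

from ponvbart.cohort import SubjectRecord, build_feature_matrix
from ponvbart.simulate import SimConfig, simulate_cohort


def make_record(**overrides):
    """One hand-built anesthetic case with sensible defaults."""
    base = dict(
        subject_id="S1", age_years=45.0, sex="female", asa_class=2,
        smoker=False, prior_ponv_or_motion_sickness=False, outpatient=True,
        cannabis_use="none", duration_min=90.0, n2o_time_fraction=0.0,
        volatile_mac_time_fraction=0.8, surgery_high_risk_nausea=False,
        n_prophylactic_antiemetics=2, pacu_opioids=True, ponv_observed=False,
    )
    base.update(overrides)
    return SubjectRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    """A small effectful synthetic cohort shared across tests."""
    records, truth = simulate_cohort(SimConfig(n=1200, seed=17),
                                     truth_mc=50_000)
    return records, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    records, _ = small_cohort
    return build_feature_matrix(records)
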