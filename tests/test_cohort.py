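import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ponvbart.cohort import (
    ColumnDialect,
    ConfigurationError,
    apply_inclusion_filters,
    build_feature_matrix,
    load_cohort,
    load_cohort_detailed,
    load_table1_fixture,
    summarize_aggregate,
    summarize_cohort,
)
from ponvbart.simulate import write_fixture

from conftest import make_record


# --- loading -----------------------------------------------------------------

def _write_csv(tmp_path, records, name="cohort.csv"):
    path = tmp_path / name
    write_fixture(records, path)
    return path


def test_load_round_trips_well_formed_rows(tmp_path):
    records = [make_record(subject_id=f"S{i}") for i in range(3)]
    path = _write_csv(tmp_path, records)
    loaded = load_cohort(path)
    assert loaded == records  # identity round-trip, order preserved


def test_past_use_maps_to_none(tmp_path):
    path = _write_csv(tmp_path, [make_record()])
    text = path.read_text().replace(",none,", ",past,")
    path.write_text(text)
    (rec,) = load_cohort(path, ColumnDialect(cannabis_values={"past": "none"}))
    assert rec.cannabis_use == "none"


def test_missing_outcome_column_is_configuration_error(tmp_path):
    path = _write_csv(tmp_path, [make_record()])
    df = pd.read_csv(path).drop(columns=["ponv_observed"])
    df.to_csv(path, index=False)
    with pytest.raises(ConfigurationError, match="ponv_observed"):
        load_cohort(path)


def test_unparseable_cell_rejects_row_with_diagnostics(tmp_path):
    good = make_record(subject_id="GOOD")
    bad = make_record(subject_id="BAD")
    path = _write_csv(tmp_path, [good, bad])
    lines = path.read_text().splitlines()
    lines[2] = lines[2].replace("45.0", "forty-five")
    path.write_text("\n".join(lines) + "\n")
    records, errors = load_cohort_detailed(path)
    assert [r.subject_id for r in records] == ["GOOD"]
    assert len(errors) == 1
    assert errors[0].row_index == 1
    assert errors[0].field == "age_years"


def test_column_dialect_maps_headers(tmp_path):
    path = _write_csv(tmp_path, [make_record()])
    text = path.read_text().replace("age_years", "AGE")
    path.write_text(text)
    (rec,) = load_cohort(path, ColumnDialect(columns={"age_years": "AGE"}))
    assert rec.age_years == 45.0


# --- inclusion filters -------------------------------------------------------

@pytest.mark.parametrize("overrides,excluded_under", [
    ({"asa_class": 4}, "asa"),
    ({"age_years": 17.9}, "age"),
    ({"duration_min": 29.9}, "duration"),
])
def test_exclusion_criteria(overrides, excluded_under):
    kept, tally = apply_inclusion_filters([make_record(**overrides)])
    assert kept == []
    assert tally[excluded_under] == 1


def test_inclusive_boundaries_are_retained():
    boundary = make_record(age_years=18.0, duration_min=30.0, asa_class=3)
    kept, tally = apply_inclusion_filters([boundary])
    assert kept == [boundary]
    assert all(v == 0 for v in tally.values())


def test_row_tripping_several_criteria_counts_under_each():
    rec = make_record(age_years=16.0, asa_class=5, duration_min=10.0)
    kept, tally = apply_inclusion_filters(
        [rec], raw_flags=[{"is_cardiac": True}])
    assert kept == []
    assert (tally["age"], tally["asa"], tally["duration"],
            tally["cardiac"]) == (1, 1, 1, 1)


def test_flag_based_exclusions():
    recs = [make_record() for _ in range(3)]
    flags = [{"anesthesia_type": "regional"}, {"is_obstetric": True},
             {"pacu_recovery": False}]
    kept, tally = apply_inclusion_filters(recs, flags)
    assert kept == []
    assert tally["anesthesia_type"] == tally["obstetric"] == \
        tally["pacu_recovery"] == 1


# --- feature encoding --------------------------------------------------------

def test_apfel_all_four_risks():
    rec = make_record(sex="female", prior_ponv_or_motion_sickness=True,
                      smoker=False, pacu_opioids=True)
    assert rec.apfel == 4


def test_apfel_no_risks():
    rec = make_record(sex="male", prior_ponv_or_motion_sickness=False,
                      smoker=True, pacu_opioids=False)
    assert rec.apfel == 0


@pytest.mark.parametrize("frac,expected", [(0.04, 0), (0.05, 0), (0.12, 1)])
def test_n2o_exposure_threshold(frac, expected):
    fm = build_feature_matrix([make_record(n2o_time_fraction=frac)])
    assert fm.X["n2o_exposed"].iloc[0] == expected


@pytest.mark.parametrize("frac,expected", [(0.10, 0), (0.15, 0), (0.16, 1)])
def test_volatile_exposure_threshold(frac, expected):
    fm = build_feature_matrix([make_record(volatile_mac_time_fraction=frac)])
    assert fm.X["volatile_exposed"].iloc[0] == expected


def test_log_duration_is_natural_log():
    fm = build_feature_matrix([make_record(duration_min=100.0)])
    assert fm.X["log_duration"].iloc[0] == pytest.approx(np.log(100.0))


def test_cannabis_dummies_mutually_exclusive(small_features):
    both = (small_features.X["cannabis_current"]
            * small_features.X["cannabis_daily"])
    assert (both == 0).all()


def test_apfel_matches_brute_force_recount(small_cohort):
    records, _ = small_cohort
    fm = build_feature_matrix(records)
    recount = (fm.X["female"] + fm.X["prior_ponv"] + fm.X["nonsmoker"]
               + fm.X["pacu_opioids"])
    assert (fm.apfel == recount.to_numpy()).all()
    assert set(np.unique(fm.apfel)) <= {0, 1, 2, 3, 4}


@settings(max_examples=20, deadline=None)
@given(st.permutations(list(range(8))))
def test_encoding_is_order_equivariant(perm):
    records = [make_record(subject_id=f"S{i}", age_years=30.0 + 3 * i,
                           sex="female" if i % 2 else "male",
                           duration_min=40.0 + 10 * i)
               for i in range(8)]
    base = build_feature_matrix(records).data
    permuted = build_feature_matrix([records[i] for i in perm]).data
    expected = base.iloc[list(perm)].reset_index(drop=True)
    pd.testing.assert_frame_equal(permuted, expected)


# --- descriptive summaries ---------------------------------------------------

def test_single_row_cohort_summary():
    rec = make_record(cannabis_use="daily", ponv_observed=True)
    out = summarize_cohort([rec])
    lvl = out["levels"]["daily"]
    assert lvl["n"] == 1
    assert lvl["pct_of_total"] == 100.0
    assert lvl["ponv_observed"] == {"n": 1, "pct": 100.0}
    assert lvl["age"]["mean"] == 45.0


def test_summary_counts_sum_to_n_and_percentages_to_100(small_cohort):
    records, _ = small_cohort
    out = summarize_cohort(records)
    assert sum(v["n"] for v in out["levels"].values()) == len(records)
    for lvl in out["levels"].values():
        asa_total = sum(v["n"] for v in lvl["asa"].values())
        assert asa_total == lvl["n"]
        pct_sum = sum(v["pct"] for v in lvl["asa"].values())
        assert pct_sum == pytest.approx(100.0, abs=0.2)  # rounding slack


def test_aggregate_fixture_reproduces_published_descriptives():
    agg = {lvl: {"n": v["n"], "ponv_observed": v["ponv_observed"],
                 "nonsmoker": v["nonsmoker"]}
           for lvl, v in load_table1_fixture().items()}
    out = summarize_aggregate(agg)
    assert out["total_n"] == 27388
    assert out["levels"]["daily"]["ponv_observed"]["pct"] == 21.9
    assert out["levels"]["current"]["ponv_observed"]["pct"] == 18.8
    assert out["levels"]["none"]["ponv_observed"]["pct"] == 17.3
    assert out["any_cannabis"]["pct"] == 10.0
    assert out["levels"]["none"]["pct_of_total"] == 90.0
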