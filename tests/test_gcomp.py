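import numpy as np
import pytest
from scipy.special import ndtr

from ponvbart.cohort import build_feature_matrix
from ponvbart.gcomp import (
    absolute_risk_table,
    build_counterfactual_grid,
    plot_sate,
    sate,
    sate_from_predictions,
)

from conftest import make_record


# --- counterfactual grid -----------------------------------------------------

def test_grid_matrices_differ_only_in_cannabis_columns(small_features):
    grid = build_counterfactual_grid(small_features)
    other = [c for c in grid.matrices["none"].columns
             if not c.startswith("cannabis_")]
    for level in ("current", "daily"):
        assert grid.matrices[level][other].equals(grid.matrices["none"][other])
    assert (grid.matrices["none"][["cannabis_current", "cannabis_daily"]]
            .to_numpy() == 0).all()
    assert (grid.matrices["daily"]["cannabis_daily"] == 1).all()
    assert (grid.matrices["daily"]["cannabis_current"] == 0).all()


def test_all_daily_cohort_forced_to_none_has_zero_dummies():
    records = [make_record(subject_id=f"S{i}", cannabis_use="daily",
                           ponv_observed=bool(i % 2)) for i in range(4)]
    grid = build_counterfactual_grid(build_feature_matrix(records))
    assert (grid.matrices["none"][["cannabis_current", "cannabis_daily"]]
            .to_numpy() == 0).all()


def test_apfel_strata_unchanged_across_levels(small_features):
    grid = build_counterfactual_grid(small_features)
    assert np.array_equal(grid.apfel, small_features.apfel)


def test_single_subject_grid_shapes():
    grid = build_counterfactual_grid(build_feature_matrix([make_record()]))
    assert all(m.shape[0] == 1 for m in grid.matrices.values())


# --- sATE arithmetic ---------------------------------------------------------

def test_identical_prediction_matrices_give_exact_null():
    p = np.full((10, 6), 0.3)
    apfel = np.array([0, 1, 2, 3, 4, 2])
    results = sate_from_predictions(
        {"none": p, "current": p.copy(), "daily": p.copy()}, apfel)
    for r in results:
        assert r.rr_mean == 1.0 and r.rd_mean == 0.0
        assert r.prob_rr_gt_1 == 0.0  # strict exceedance at a tie


def test_two_draw_arithmetic_example():
    # treated stratum means {0.22, 0.24}, control {0.20, 0.20}
    control = np.array([[0.20] * 4, [0.20] * 4])
    treated = np.array([[0.22] * 4, [0.24] * 4])
    apfel = np.zeros(4, dtype=int)
    results = sate_from_predictions(
        {"none": control, "daily": treated, "current": control},
        apfel, contrasts=("daily_vs_none",), stratify=False)
    (r,) = results
    assert r.rr_mean == pytest.approx(1.15)
    assert r.rd_mean == pytest.approx(0.03)
    assert r.prob_rr_gt_1 == 1.0
    assert r.rr_ci_low <= r.rr_mean <= r.rr_ci_high
    assert r.rd_ci_low <= r.rd_mean <= r.rd_ci_high


def test_pooled_mean_is_subject_weighted_average_of_strata():
    rng = np.random.default_rng(0)
    n, draws = 60, 8
    apfel = rng.integers(0, 5, n)
    preds = {lv: rng.uniform(0.05, 0.6, size=(draws, n))
             for lv in ("none", "current", "daily")}
    results = sate_from_predictions(preds, apfel)
    pooled = {r.contrast: r for r in results if r.stratum == "pooled"}
    for contrast, pr in pooled.items():
        strata = [r for r in results
                  if r.contrast == contrast and r.stratum != "pooled"]
        w = np.array([r.n_subjects for r in strata], dtype=float)
        assert pr.p_treated_mean == pytest.approx(
            np.average([r.p_treated_mean for r in strata], weights=w))
        assert pr.p_control_mean == pytest.approx(
            np.average([r.p_control_mean for r in strata], weights=w))


def test_positive_latent_shift_strictly_increases_rr_each_draw():
    rng = np.random.default_rng(1)
    latent = rng.normal(-1.0, 0.5, size=(12, 40))
    base = {"none": ndtr(latent), "daily": ndtr(latent),
            "current": ndtr(latent)}
    shifted = dict(base, daily=ndtr(latent + 0.3))
    apfel = np.zeros(40, dtype=int)
    r0 = sate_from_predictions(base, apfel, contrasts=("daily_vs_none",),
                               stratify=False)[0]
    r1 = sate_from_predictions(shifted, apfel, contrasts=("daily_vs_none",),
                               stratify=False)[0]
    assert r1.rr_mean > r0.rr_mean
    assert r1.prob_rr_gt_1 == 1.0


def test_empty_stratum_is_omitted(caplog):
    p = np.full((5, 3), 0.2)
    apfel = np.array([0, 0, 1])  # strata 2-4 empty
    results = sate_from_predictions({"none": p, "current": p, "daily": p},
                                    apfel)
    strata = {r.stratum for r in results}
    assert strata == {"pooled", 0, 1}


# --- reporting ---------------------------------------------------------------

def _mk_result(rd_mean, **kw):
    from ponvbart.gcomp import SateResult
    base = dict(contrast="daily_vs_none", stratum="pooled", rr_mean=1.2,
                rr_ci_low=1.0, rr_ci_high=1.45, rd_mean=rd_mean,
                rd_ci_low=rd_mean - 0.03, rd_ci_high=rd_mean + 0.03,
                prob_rr_gt_1=0.97, n_draws=100, n_subjects=50)
    base.update(kw)
    return SateResult(**base)


@pytest.mark.parametrize("rd,expected", [
    (0.033, "3.3%"),
    (0.0, "0.0%"),
    (-0.007, "-0.7%"),
])
def test_absolute_risk_table_percent_formatting(rd, expected):
    table = absolute_risk_table([_mk_result(rd)])
    assert table["risk_increase_pct"].iloc[0] == expected
    assert table["rd_mean"].iloc[0] == rd  # raw value preserved


def test_plot_sate_writes_figures(tmp_path):
    results = [_mk_result(0.03, stratum=s) for s in [0, 1, 2, 3, 4, "pooled"]]
    results += [_mk_result(0.01, stratum=s, contrast="current_vs_none")
                for s in [0, 1, 2, 3, 4, "pooled"]]
    paths = plot_sate(results, tmp_path, formats=("svg", "png"))
    assert len(paths) == 4
    assert all(p.exists() and p.stat().st_size > 0 for p in paths)


def test_plot_sate_pooled_only(tmp_path):
    paths = plot_sate([_mk_result(0.02)], tmp_path)
    assert all(p.exists() for p in paths)
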