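import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from ponvbart.cohort import build_feature_matrix
from ponvbart.gcomp import build_counterfactual_grid
from ponvbart.propensity import (
    LogisticPosterior,
    OUTCOME_DESIGN_COLUMNS,
    fit_bayes_logistic,
    fit_outcome_logistic,
    fit_propensity,
    logistic_sate,
    or_table,
)
from ponvbart.simulate import SimConfig, simulate_cohort, _assignment_probs

from conftest import make_record


# --- core Bayesian logistic sampler -----------------------------------------

@pytest.fixture(scope="module")
def logistic_fit():
    rng = np.random.default_rng(0)
    n = 2000
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    beta_true = np.array([-1.0, 0.5, -0.3, 0.8])
    y = (rng.uniform(size=n) < expit(X @ beta_true)).astype(float)
    post = fit_bayes_logistic(X, y, ["intercept", "a", "b", "c"],
                              draws=1000, chains=2, seed=1)
    return post


def test_posterior_mean_agrees_with_map_within_mcse(logistic_fit):
    """The MCMC mean must sit within 3 Monte-Carlo standard errors (batch
    means) of the deterministic penalized-likelihood mode."""
    post = logistic_fit
    pm = post.draws.mean(axis=0)
    batches = post.draws.reshape(20, -1, post.draws.shape[1]).mean(axis=1)
    mcse = batches.std(axis=0, ddof=1) / np.sqrt(20)
    assert (np.abs(pm - post.map_estimate) <= 3 * mcse).all()


def test_split_rhat_below_threshold(logistic_fit):
    assert np.nanmax(logistic_fit.rhat) < 1.05


def test_posterior_recovers_contingency_table_odds_ratio():
    # single binary covariate at n=4000: posterior OR ~ the closed-form
    # sample odds ratio
    rng = np.random.default_rng(4)
    n = 4000
    x = rng.integers(0, 2, n).astype(float)
    y = (rng.uniform(size=n) < np.where(x == 1, 0.45, 0.25)).astype(float)
    a = ((x == 1) & (y == 1)).sum()
    b = ((x == 1) & (y == 0)).sum()
    c = ((x == 0) & (y == 1)).sum()
    d = ((x == 0) & (y == 0)).sum()
    sample_or = (a * d) / (b * c)
    X = np.column_stack([np.ones(n), x])
    post = fit_bayes_logistic(X, y, ["intercept", "x"], draws=1000,
                              chains=2, seed=2)
    post_or = np.exp(post.draws[:, 1]).mean()
    assert post_or == pytest.approx(sample_or, rel=0.05)


# --- propensity scores -------------------------------------------------------

def test_intercept_only_propensity_equals_prevalence():
    # constant covariates: every propensity collapses to the prevalence
    records = [make_record(subject_id=f"S{i}",
                           cannabis_use="daily" if i < 3 else "none")
               for i in range(30)]
    features = build_feature_matrix(records)
    p = fit_propensity(features, seed=0, draws=600)
    assert p.shape == (30,)
    assert ((p > 0) & (p < 1)).all()
    assert np.allclose(p, p[0])
    assert p[0] == pytest.approx(0.1, abs=0.04)


@pytest.fixture(scope="module")
def confounded_cohort():
    cfg = SimConfig(n=4000, seed=23)
    records, truth = simulate_cohort(cfg, truth_mc=50_000)
    return cfg, records, truth


def test_estimated_propensity_ranks_match_truth(confounded_cohort):
    cfg, records, _ = confounded_cohort
    features = build_feature_matrix(records)
    est = fit_propensity(features, seed=3, draws=600)
    cov = pd.DataFrame({
        "female": [r.sex == "female" for r in records],
        "smoker": [r.smoker for r in records],
        "prior_ponv": [r.prior_ponv_or_motion_sickness for r in records],
        "pacu_opioids": [r.pacu_opioids for r in records],
        "age_years": [r.age_years for r in records],
        "asa_class": [r.asa_class for r in records],
    })
    true_prop = 1.0 - _assignment_probs(cov, cfg.assignment_coefs)[:, 0]
    rho = spearmanr(est, true_prop).statistic
    assert rho > 0.9


def test_bart_engine_returns_valid_propensities(small_features):
    p = fit_propensity(small_features, engine="bart", seed=1)
    assert ((p > 0) & (p < 1)).all()


# --- outcome model and OR table ----------------------------------------------

@pytest.fixture(scope="module")
def outcome_posterior(confounded_cohort):
    _, records, _ = confounded_cohort
    features = build_feature_matrix(records)
    prop = fit_propensity(features, seed=5, draws=600)
    post = fit_outcome_logistic(features, prop, draws=800, chains=2, seed=6)
    return features, prop, post


def test_or_table_layout_and_reference_rows(outcome_posterior):
    _, _, post = outcome_posterior
    table = or_table(post)
    assert len(table) == 16
    ref = table[table["parameter"].str.contains("Reference|Referent")]
    assert (ref["odds_ratio"] == 1.0).all()
    assert ref["ci_low"].isna().all()
    others = table[~table["parameter"].str.contains("Reference|Referent")]
    assert (others["ci_low"] <= others["odds_ratio"]).all()
    assert (others["odds_ratio"] <= others["ci_high"]).all()
    assert table["parameter"].iloc[0] == "Age < 50 years"
    assert "Propensity Score" in table["parameter"].iloc[14]


def test_outcome_model_recovers_risk_factor_directions(outcome_posterior):
    _, _, post = outcome_posterior
    table = or_table(post).set_index("parameter")
    # strong generating effects must come out with OR > 1
    for label in ("Female Sex", "Exposed to Potent Volatile Agent",
                  "Non-smoker"):
        assert table.loc[label, "odds_ratio"] > 1.0
    assert table.loc["Per Prophylactic PONV Drug Given", "odds_ratio"] < 1.0


def test_non_finite_propensity_rejected(small_features):
    prop = np.full(len(small_features), 0.1)
    prop[0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_outcome_logistic(small_features, prop)


def test_null_outcome_model_covers_one_in_most_parameters():
    """With no generating effects at all, the 95% credible intervals of the
    13 non-reference odds ratios should almost all cover 1."""
    cfg = SimConfig(n=3000, seed=31)
    cfg.outcome_coefs = {k: (v if k == "intercept" else 0.0)
                         for k, v in cfg.outcome_coefs.items()}
    records, _ = simulate_cohort(cfg, truth_mc=10_000)
    features = build_feature_matrix(records)
    prop = fit_propensity(features, seed=7, draws=600)
    post = fit_outcome_logistic(features, prop, draws=800, chains=2, seed=8)
    table = or_table(post)
    rows = table[~table["parameter"].str.contains("Reference|Referent")]
    # the propensity row is excluded: under a null outcome it is still a
    # function of covariates only, so its interval behaves like the rest
    covered = ((rows["ci_low"] <= 1.0) & (1.0 <= rows["ci_high"])).sum()
    assert covered >= 11


# --- logistic g-computation ---------------------------------------------------

def _hand_posterior(features, coefs_by_name, propensity_pct):
    draws = np.array([[coefs_by_name.get(c, 0.0)
                       for c in OUTCOME_DESIGN_COLUMNS]])
    return LogisticPosterior(
        draws=draws, columns=list(OUTCOME_DESIGN_COLUMNS),
        prior_scale=np.ones(draws.shape[1]), seed=0,
        map_estimate=draws[0], rhat=np.ones(draws.shape[1]),
        accept_rate=1.0, propensity_pct=propensity_pct)


def test_zero_cannabis_coefficients_give_rr_exactly_one(small_features):
    post = _hand_posterior(small_features, {"intercept": -1.5},
                           np.full(len(small_features), 10.0))
    grid = build_counterfactual_grid(small_features)
    results = logistic_sate(post, grid)
    for r in results:
        assert r.rr_mean == 1.0
        assert r.rd_mean == 0.0


def test_single_draw_hand_computation(small_features):
    coefs = {"intercept": -2.0, "cannabis_daily": 0.5, "female": 0.3}
    pct = np.full(len(small_features), 10.0)
    post = _hand_posterior(small_features, coefs, pct)
    grid = build_counterfactual_grid(small_features)
    (r_cur, r_daily) = logistic_sate(post, grid)
    female = small_features.X["female"].to_numpy()
    p_none = expit(-2.0 + 0.3 * female)
    p_daily = expit(-2.0 + 0.5 + 0.3 * female)
    assert r_daily.rr_mean == pytest.approx(p_daily.mean() / p_none.mean())
    assert r_daily.rd_mean == pytest.approx(p_daily.mean() - p_none.mean())
    assert r_cur.rr_mean == pytest.approx(1.0)
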