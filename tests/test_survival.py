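import numpy as np
import pandas as pd
import pytest

from pemtscope.io import ClinicalTable, ValidationError
from pemtscope.survival import (
    HIGH,
    LOW,
    MIDDLE,
    cox_multivariable,
    cox_univariable_screen,
    dichotomize_by_quantiles,
    km_logrank,
    stratified_km,
)


def clinical_from(time, event, **covs):
    idx = [f"s{i}" for i in range(len(time))]
    return ClinicalTable(pd.DataFrame({"time": time, "event": event, **covs}, index=idx))


def sim_clinical(n, log_hr, seed, covariate=None):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) if covariate is None else np.asarray(covariate)
    hazard = 0.05 * np.exp(log_hr * x)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / 0.02, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return clinical_from(np.maximum(time, 1e-9), event, x=x)


# ---------------------------------------------------------------------------
# dichotomization


def test_forty_forty_split_on_1_to_10():
    scores = pd.Series(range(1, 11), index=[f"s{i}" for i in range(10)], dtype=float)
    strat = dichotomize_by_quantiles(scores, 0.4, 0.6)
    assert strat.samples_in(LOW) == [f"s{i}" for i in range(4)]
    assert sorted(strat.samples_in(HIGH)) == [f"s{i}" for i in range(6, 10)]
    assert sorted(strat.samples_in(MIDDLE)) == ["s4", "s5"]


def test_median_split_has_no_middle():
    scores = pd.Series(range(1, 11), index=[f"s{i}" for i in range(10)], dtype=float)
    strat = dichotomize_by_quantiles(scores, 0.5, 0.5)
    assert len(strat.samples_in(MIDDLE)) == 0
    assert len(strat.samples_in(LOW)) == 5 and len(strat.samples_in(HIGH)) == 5


def test_boundary_ties_resolved_by_sample_id():
    scores = pd.Series([1, 2, 2, 2, 5], index=list("abcde"), dtype=float)
    strat = dichotomize_by_quantiles(scores, 0.4, 0.6)
    # group sizes stay at their type-7 position counts despite the ties
    assert len(strat.samples_in(LOW)) == 2
    assert len(strat.samples_in(HIGH)) == 2
    assert strat.samples_in(LOW) == ["a", "b"]  # tie at 2 admitted by id order


def test_all_equal_scores_error():
    scores = pd.Series([3.0, 3.0, 3.0, 3.0], index=list("abcd"))
    with pytest.raises(ValidationError, match="degenerate"):
        dichotomize_by_quantiles(scores)


# ---------------------------------------------------------------------------
# Cox models


def test_null_group_indicator_hr_near_one():
    rng = np.random.default_rng(0)
    t = rng.exponential(10.0, size=400)
    clin = clinical_from(t, np.ones(400, dtype=int), grp=(np.arange(400) % 2).astype(float))
    fits = cox_univariable_screen(clin, ["grp"])
    tab = fits[0].table
    assert tab["ci_low"].iloc[0] <= 1.0 <= tab["ci_high"].iloc[0]


def test_true_hr2_ci_coverage():
    clin = sim_clinical(800, np.log(2.0), seed=7)
    fits = cox_univariable_screen(clin, ["x"])
    tab = fits[0].table
    assert tab["ci_low"].iloc[0] <= 2.0 <= tab["ci_high"].iloc[0]


def test_risk_factor_mode_requires_hr_above_one():
    clin = sim_clinical(500, -1.0, seed=3)  # strongly protective covariate
    two_sided = cox_univariable_screen(clin, ["x"], risk_factor_mode=False)
    risk_only = cox_univariable_screen(clin, ["x"], risk_factor_mode=True)
    assert bool(two_sided[0].table["relevant"].iloc[0])
    assert not bool(risk_only[0].table["relevant"].iloc[0])


def test_multivariable_single_term_matches_univariable():
    clin = sim_clinical(300, 0.5, seed=11)
    uni = cox_univariable_screen(clin, ["x"])[0]
    multi = cox_multivariable(clin, ["x"])
    assert multi.table["hr"].iloc[0] == pytest.approx(uni.table["hr"].iloc[0], abs=1e-8)
    assert multi.aic == pytest.approx(uni.aic, abs=1e-8)


def test_multivariable_null_term_ci_covers_one():
    rng = np.random.default_rng(99)
    clin = sim_clinical(600, 0.7, seed=13)
    df = clin.data.copy()
    df["noise"] = rng.standard_normal(len(df))
    clin2 = ClinicalTable(df)
    fit = cox_multivariable(clin2, ["x", "noise"])
    assert fit.table.loc["noise", "ci_low"] <= 1.0 <= fit.table.loc["noise", "ci_high"]
    assert not (fit.table.loc["x", "ci_low"] <= 1.0 <= fit.table.loc["x", "ci_high"])


def test_collinear_duplicate_covariate_errors():
    clin = sim_clinical(200, 0.5, seed=2)
    df = clin.data.copy()
    df["x2"] = 2.0 * df["x"]
    with pytest.raises(ValidationError, match="collinear"):
        cox_multivariable(ClinicalTable(df), ["x", "x2"])


def test_hr_transforms_exactly_under_covariate_rescaling():
    clin = sim_clinical(300, 0.6, seed=21)
    fit1 = cox_multivariable(clin, ["x"])
    df = clin.data.copy()
    df["x"] = df["x"] / 2.0
    fit2 = cox_multivariable(ClinicalTable(df), ["x"])
    assert fit2.hr.iloc[0] == pytest.approx(fit1.hr.iloc[0] ** 2, rel=1e-6)


# ---------------------------------------------------------------------------
# Kaplan-Meier / logrank


def test_km_equals_empirical_survival_without_censoring():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    clin = clinical_from(t, np.ones(5, dtype=int))
    groups = pd.Series(["a", "a", "a", "b", "b"], index=clin.sample_ids)
    strat = km_logrank(clin, groups)
    a = strat.curves[strat.curves["group"] == "a"].set_index("time")["survival"]
    # empirical: S(1)=2/3, S(2)=1/3, S(3)=0
    assert a.loc[1.0] == pytest.approx(2 / 3)
    assert a.loc[2.0] == pytest.approx(1 / 3)
    assert a.loc[3.0] == pytest.approx(0.0)


def test_logrank_zero_statistic_on_duplicated_groups():
    t = np.array([2.0, 5.0, 7.0, 9.0] * 2)
    e = np.array([1, 0, 1, 1] * 2)
    clin = clinical_from(t, e)
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=clin.sample_ids)
    strat = km_logrank(clin, groups)
    assert strat.logrank_p == pytest.approx(1.0, abs=1e-9)


def test_logrank_power_when_one_group_always_later():
    t = np.concatenate([np.arange(1, 51), np.arange(101, 151)]).astype(float)
    clin = clinical_from(t, np.ones(100, dtype=int))
    groups = pd.Series(["early"] * 50 + ["late"] * 50, index=clin.sample_ids)
    strat = km_logrank(clin, groups)
    assert strat.logrank_p < 0.01


def test_median_undefined_when_curve_stays_high():
    t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    e = np.array([1, 1, 1, 0, 0, 0])
    clin = clinical_from(t, e)
    groups = pd.Series(["dies", "dies", "dies", "alive", "alive", "alive"],
                       index=clin.sample_ids)
    strat = km_logrank(clin, groups)
    assert strat.median_survival["alive"] is None
    assert strat.median_survival["dies"] is not None


def test_stratified_collapses_when_factor_constant():
    clin = sim_clinical(60, 0.8, seed=5)
    df = clin.data.copy()
    df["flag"] = "yes"
    clin2 = ClinicalTable(df)
    groups = pd.Series([LOW] * 30 + [HIGH] * 30, index=clin2.sample_ids)
    plain = km_logrank(clin2, groups)
    strat = stratified_km(clin2, groups, "flag")
    assert strat.logrank_p == pytest.approx(plain.logrank_p)


def test_stratified_additive_hazards_order_medians():
    rng = np.random.default_rng(8)
    n = 400
    score_high = np.repeat([0, 1], n // 2)
    nodal = np.tile([0, 1], n // 2)
    loghaz = np.log(0.02) + 0.9 * score_high + 0.9 * nodal
    t = rng.exponential(1.0 / np.exp(loghaz))
    clin = clinical_from(t, np.ones(n, dtype=int), nodal=nodal.astype(float))
    groups = pd.Series(np.where(score_high == 1, HIGH, LOW), index=clin.sample_ids)
    strat = stratified_km(clin, groups, "nodal")
    med = strat.median_survival
    assert med["low/0.0"] > med["high/0.0"] > med["high/1.0"]
    assert med["low/0.0"] > med["low/1.0"] > med["high/1.0"]


def test_stratified_empty_cell_errors():
    clin = sim_clinical(40, 0.5, seed=6)
    df = clin.data.copy()
    df["flag"] = ["A"] * 20 + ["B"] * 20
    clin2 = ClinicalTable(df)
    groups = pd.Series([LOW] * 20 + [HIGH] * 20, index=clin2.sample_ids)
    # low only ever co-occurs with A, so the cross has empty cells
    with pytest.raises(ValidationError, match="empty stratification cell"):
        stratified_km(clin2, groups, "flag")
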