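"""Stratified Cox fitter tests: grid-search partial-likelihood oracle,
cross-checks against lifelines, Breslow baseline survival, pooling, and
leave-one-region-out cross-validation."""

import math

import numpy as np
import pandas as pd
import pytest

from ckbcvd import (
    fit_stratified_cox,
    internal_external_cv,
    pool_baseline_survival,
)
from ckbcvd.derivation import FittingError, validate_cohort
from ckbcvd.model_core import design_matrix, risk_from_lp


# ---------------------------------------------------------------------------
# partial-likelihood oracle
# ---------------------------------------------------------------------------

def _toy_partial_loglik(beta, rows_by_region):
    """Hand-written stratified partial log-likelihood (no ties, one covariate)."""
    total = 0.0
    for rows in rows_by_region:
        for t_i, e_i, x_i in rows:
            if e_i:
                denom = sum(math.exp(beta * x) for t, _, x in rows if t >= t_i)
                total += beta * x_i - math.log(denom)
    return total


def test_fitter_matches_grid_search_maximizer(toy_cohort):
    region1 = [(1.0, 1, 1.0), (2.0, 0, 0.0), (3.0, 1, 0.0), (4.0, 0, 1.0)]
    region2 = [(1.5, 1, 1.0), (2.5, 1, 1.0), (3.5, 0, 0.0), (4.5, 0, 0.0)]
    rows = region1 + region2
    cohort = toy_cohort(
        time=[r[0] for r in rows],
        event=["IHD" if r[1] else "none" for r in rows],
        region=[1] * 4 + [2] * 4,
        x=[r[2] for r in rows],
    )
    fit = fit_stratified_cox(cohort, "IHD", predictors=["x"],
                             age_interactions=False)
    grid = np.arange(-3.0, 3.0, 1e-4)
    values = [_toy_partial_loglik(b, [region1, region2]) for b in grid]
    best = grid[int(np.argmax(values))]
    assert abs(fit.beta[0] - best) < 1e-3
    assert fit.converged and fit.gradient_norm < 1e-7


def test_constant_covariate_gets_zero_beta_and_infinite_variance(small_female_cohort):
    sub = small_female_cohort[small_female_cohort["region"] == 1].head(800).copy()
    sub["x"] = 1.0
    fit = fit_stratified_cox(sub, "IHD", predictors=["age", "x"],
                             age_interactions=False)
    assert "x" in fit.zero_variance
    assert fit.coefficients.beta_main["x"] == 0.0
    assert fit.standard_errors["x"] == np.inf
    assert np.isfinite(fit.standard_errors["age"])


def test_single_region_fit_matches_unstratified_lifelines(small_female_cohort):
    """With one region the stratified fit is an ordinary Cox fit; lifelines
    serves as the independent implementation."""
    from lifelines import CoxPHFitter

    sub = small_female_cohort[small_female_cohort["region"] == 2]
    fit = fit_stratified_cox(sub, "IHD", sex="female")
    X, cols = design_matrix(sub)
    df = pd.DataFrame(X, columns=[c.replace(":", "_") for c in cols])
    df["T"] = sub["time"].to_numpy()
    df["E"] = (sub["event"] == "IHD").to_numpy().astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    for j, c in enumerate(cols):
        assert fit.beta[j] == pytest.approx(cph.params_[c.replace(":", "_")], abs=1e-4)
        assert fit.standard_errors[c] == pytest.approx(
            cph.standard_errors_[c.replace(":", "_")], rel=1e-3)


def test_efron_ties_match_lifelines(toy_cohort):
    """Tied event times exercise the Efron correction; lifelines (Efron by
    default) is the cross-check."""
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(7)
    n = 200
    x = rng.normal(size=n)
    t = np.ceil(rng.exponential(5, n) * 2) / 2  # coarse grid -> many ties
    e = rng.random(n) < 0.7
    cohort = toy_cohort(time=t, event=np.where(e, "IHD", "none"), region=1, x=x)
    fit = fit_stratified_cox(cohort, "IHD", predictors=["x"], age_interactions=False)
    cph = CoxPHFitter()
    cph.fit(pd.DataFrame({"x": x, "T": t, "E": e.astype(int)}), "T", "E")
    assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-5)


def test_no_target_events_raises(toy_cohort):
    cohort = toy_cohort(time=[1, 2, 3, 4], event=["none"] * 4, region=1,
                        x=[0.0, 1.0, 0.0, 1.0])
    with pytest.raises(FittingError, match="no IHD events"):
        fit_stratified_cox(cohort, "IHD", predictors=["x"], age_interactions=False)


# ---------------------------------------------------------------------------
# baseline survival
# ---------------------------------------------------------------------------

def test_baseline_survival_exponential_oracle(toy_cohort):
    """All-zero betas reduce Breslow to Nelson-Aalen; for exponential event
    times with rate lam, S0(10) -> exp(-10*lam)."""
    rng = np.random.default_rng(3)
    n, lam = 4000, 0.02
    t_event = rng.exponential(1 / lam, n)
    censor = 12.0
    time = np.minimum(t_event, censor)
    event = np.where(t_event <= censor, "IHD", "none")
    cohort = toy_cohort(time=time, event=event, region=1)
    fit = fit_stratified_cox(cohort, "IHD")  # every predictor constant
    assert set(fit.zero_variance) == set(fit.columns)
    assert fit.per_region_s0[1] == pytest.approx(math.exp(-10 * lam), abs=0.02)
    # single region pools to itself (up to the weighted-mean division)
    assert fit.coefficients.s0_10 == pytest.approx(fit.per_region_s0[1], rel=1e-14)


def test_region_without_events_has_unit_baseline_survival(toy_cohort):
    rng = np.random.default_rng(4)
    n = 300
    t1 = np.minimum(rng.exponential(20, n), 11.0)
    cohort1 = toy_cohort(time=t1, event=np.where(t1 < 11.0, "IHD", "none"),
                         region=1, x=rng.normal(size=n))
    cohort2 = toy_cohort(time=np.full(50, 11.0), event=["none"] * 50, region=2,
                         x=rng.normal(size=50))
    cohort2["id"] += n
    cohort = pd.concat([cohort1, cohort2], ignore_index=True)
    with pytest.warns(UserWarning, match="no"):
        fit = fit_stratified_cox(cohort, "IHD", predictors=["x"],
                                 age_interactions=False)
    assert fit.per_region_s0[2] == 1.0
    assert fit.case_counts[2] == 0
    # pooling weighted by events by 10 years ignores the empty region
    assert fit.coefficients.s0_10 == pytest.approx(fit.per_region_s0[1], rel=1e-14)


def test_pool_baseline_survival_arithmetic():
    assert pool_baseline_survival({1: 0.9, 2: 0.8}, {1: 5, 2: 5}) == pytest.approx(0.85)
    assert pool_baseline_survival({1: 0.9, 2: 0.8}, {1: 7, 2: 0}) == pytest.approx(0.9)
    assert pool_baseline_survival(
        {1: 0.92, 2: 0.88}, {1: 3, 2: 1}) == pytest.approx(0.91, abs=1e-12)


def test_pool_baseline_survival_errors():
    with pytest.raises(ValueError, match="zero"):
        pool_baseline_survival({1: 0.9}, {1: 0})
    with pytest.raises(ValueError, match="keys"):
        pool_baseline_survival({1: 0.9}, {2: 3})


def test_pooled_survival_between_min_and_max(small_male_cohort):
    fit = fit_stratified_cox(small_male_cohort, "IS", sex="male")
    values = list(fit.per_region_s0.values())
    assert min(values) <= fit.coefficients.s0_10 <= max(values)
    assert all(0 < v < 1 for v in values)


# ---------------------------------------------------------------------------
# internal-external cross-validation
# ---------------------------------------------------------------------------

def test_cv_null_model_has_chance_concordance(toy_cohort):
    rng = np.random.default_rng(5)
    n = 180
    t = rng.exponential(8, n)
    e = rng.random(n) < 0.5
    cohort = toy_cohort(time=t, event=np.where(e, "IHD", "none"),
                        region=np.repeat([1, 2, 3], n // 3), x=1.0)
    res = internal_external_cv(cohort, "IHD", predictors=["x"],
                               age_interactions=False)
    assert res.pooled_c == pytest.approx(0.5, abs=1e-12)
    assert (res.per_region["c"] == 0.5).all()


def _brute_force_c(r, t, d):
    num = den = 0.0
    for i in range(len(r)):
        for j in range(len(r)):
            if i == j:
                continue
            if d[i] and (t[i] < t[j] or (t[i] == t[j] and not d[j])):
                den += 1
                num += 1.0 if r[i] > r[j] else 0.5 if r[i] == r[j] else 0.0
    return num / den


def test_cv_pooled_c_matches_pair_enumeration(toy_cohort):
    """Per-region C from the CV equals brute-force pair enumeration, and the
    pooled value equals the inverse-variance combination of regional values."""
    rng = np.random.default_rng(6)
    n_per, regions = 40, [1, 2, 3]
    frames = []
    for k, reg in enumerate(regions):
        x = rng.normal(size=n_per)
        t = rng.exponential(np.exp(-0.8 * x) * 8)
        censor = rng.uniform(4, 15, n_per)
        time = np.minimum(t, censor)
        event = np.where(t <= censor, "IHD", "none")
        f = toy_cohort(time=time, event=event, region=reg, x=x)
        f["id"] += k * n_per
        frames.append(f)
    cohort = pd.concat(frames, ignore_index=True)
    res = internal_external_cv(cohort, "IHD", predictors=["x"],
                               age_interactions=False)
    for _, row in res.per_region.iterrows():
        reg = row["region"]
        train = cohort[cohort["region"] != reg]
        test = cohort[cohort["region"] == reg]
        fit = fit_stratified_cox(train, "IHD", predictors=["x"],
                                 age_interactions=False)
        risks = np.asarray(risk_from_lp(
            test["x"].to_numpy() * fit.beta[0], fit.coefficients.s0_10))
        oracle = _brute_force_c(risks, test["time"].to_numpy(),
                                (test["event"] == "IHD").to_numpy())
        assert row["c"] == pytest.approx(oracle, abs=1e-12)
    w = 1.0 / np.maximum(res.per_region["se"].to_numpy(), 1e-10) ** 2
    pooled = np.sum(w * res.per_region["c"]) / np.sum(w)
    assert res.pooled_c == pytest.approx(pooled, abs=1e-12)


def test_cv_requires_three_regions(toy_cohort):
    cohort = toy_cohort(time=[1, 2, 3, 4], event=["IHD"] * 4,
                        region=[1, 1, 2, 2], x=[0.1, 0.2, 0.3, 0.4])
    with pytest.raises(ValueError, match="3 regions"):
        internal_external_cv(cohort, "IHD", predictors=["x"],
                             age_interactions=False)


def test_validate_cohort_rejects_bad_tables(toy_cohort):
    good = toy_cohort(time=[1, 2], event=["IHD", "none"], region=1)
    validate_cohort(good)
    with pytest.raises(ValueError, match="event"):
        validate_cohort(good.assign(event=["IHD", "stroke?"]))
    with pytest.raises(ValueError, match="time"):
        validate_cohort(good.assign(time=[1.0, 0.0]))
    with pytest.raises(ValueError, match="columns"):
        validate_cohort(good.drop(columns=["waist"]))
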