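"""Re-derivation of the risk models from individual cohort data.

Fits cause-specific Cox proportional-hazards models stratified by study
region with time-on-study as the time scale.  Subjects whose first event is
a different CVD type, an unspecified stroke, or a non-CVD death are censored
at that time for the target outcome (cause-specific hazards).  Baseline
survival at 10 years is estimated per region from the Breslow cumulative
baseline hazard evaluated at the centered covariate origin, then pooled
across regions weighted by the number of target-outcome events occurring by
10 years.

The fitter is a Newton–Raphson maximizer of the stratified partial
likelihood with the Efron tie correction and step-halving; convergence
requires max |gradient| < 1e-7 and a relative log-likelihood change < 1e-9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CENTERS,
    OUTCOMES,
    PREDICTORS,
    CoefficientSet,
    beta_vector,
    design_matrix,
    linear_predictor_frame,
    risk_from_lp,
)
from .evaluation import harrell_c

EVENT_LABELS = ("none", "IHD", "IS", "HS", "unspecified_stroke", "death_other")

COHORT_COLUMNS = (
    "id", "region", "sex", "age", "sbp", "dbp",
    "bp_treatment", "daily_smoker", "diabetes", "waist", "time", "event",
)


class FittingError(RuntimeError):
    """Partial-likelihood maximization failed; carries diagnostics."""


def validate_cohort(df: pd.DataFrame) -> None:
    """Check the cohort-table contract (columns, event labels, positive times)."""
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad = set(df["event"].unique()) - set(EVENT_LABELS)
    if bad:
        raise ValueError(f"unknown event labels: {sorted(bad)}")
    if (df["time"] <= 0).any():
        n = int((df["time"] <= 0).sum())
        raise ValueError(f"{n} rows have non-positive follow-up time")
    if df["id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort table")


@dataclass
class FitResult:
    """A fitted cause-specific submodel with uncertainty and diagnostics."""

    coefficients: CoefficientSet
    standard_errors: dict[str, float]
    per_region_s0: dict[object, float]
    case_counts: dict[object, int]
    n_subjects: int
    n_events: int
    log_likelihood: float
    n_iter: int
    gradient_norm: float
    converged: bool
    zero_variance: list[str] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)
    beta: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.coefficients.outcome,
            "sex": self.coefficients.sex,
            "beta": {c: float(b) for c, b in zip(self.columns, self.beta)},
            "se": {c: float(s) for c, s in self.standard_errors.items()},
            "s0_10_pooled": self.coefficients.s0_10,
            "per_region_s0": {str(r): float(s) for r, s in self.per_region_s0.items()},
            "case_counts": {str(r): int(c) for r, c in self.case_counts.items()},
            "n_subjects": self.n_subjects,
            "n_events": self.n_events,
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "gradient_norm": self.gradient_norm,
            "converged": self.converged,
            "zero_variance": list(self.zero_variance),
        }


# ---------------------------------------------------------------------------
# stratified partial likelihood (Efron ties)
# ---------------------------------------------------------------------------

class _Stratum:
    """Sorted per-region data plus the event tie-group structure.

    Risk-set suffix sums are only ever needed at the first at-risk row of
    each distinct event time, so they are accumulated from segment sums
    between consecutive boundaries (``np.add.reduceat``) rather than from
    full-length cumulative sums.
    """

    def __init__(self, time: np.ndarray, d: np.ndarray, X: np.ndarray):
        order = np.argsort(time, kind="stable")
        self.t = time[order]
        self.d = d[order].astype(bool)
        self.X = X[order]
        self.ev = np.flatnonzero(self.d)
        te = self.t[self.ev]
        if len(te):
            new = np.empty(len(te), dtype=bool)
            new[0] = True
            new[1:] = te[1:] != te[:-1]
            self.g_of_event = np.cumsum(new) - 1
            self.g_time = te[new]
            self.g_size = np.bincount(self.g_of_event)
            # first at-risk row for each tie group (risk set = rows >= start)
            self.g_start = np.searchsorted(self.t, self.g_time, side="left")
        else:
            self.g_time = np.empty(0)
            self.g_size = np.empty(0, dtype=int)
            self.g_start = np.empty(0, dtype=int)
            self.g_of_event = np.empty(0, dtype=int)
        n, p = self.X.shape
        self.XX2 = (self.X[:, :, None] * self.X[:, None, :]).reshape(n, p * p)


def _suffix_at(arr: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Suffix sums of ``arr`` rows evaluated at ascending boundary rows."""
    seg = np.add.reduceat(arr, boundaries, axis=0)
    return np.cumsum(seg[::-1], axis=0)[::-1]


def _stratum_ll_grad_info(beta: np.ndarray, s: _Stratum, ll_only: bool = False):
    """Efron partial log-likelihood, gradient and information for one stratum."""
    p = s.X.shape[1]
    if len(s.g_start) == 0:
        return 0.0, np.zeros(p), np.zeros((p, p))
    eta = s.X @ beta
    with np.errstate(over="ignore"):
        w = np.exp(eta)
    if not np.all(np.isfinite(w)):
        return -np.inf, np.zeros(p), np.zeros((p, p))
    B = s.g_start
    S0 = _suffix_at(w[:, None], B)[:, 0]
    ll = float(eta[s.ev].sum())
    grad = np.zeros(p)
    info = np.zeros((p, p))
    singles = s.g_size == 1
    tied = np.flatnonzero(~singles)
    if ll_only and len(tied) == 0:
        return ll - float(np.log(S0).sum()), grad, info

    wX = w[:, None] * s.X
    if ll_only:
        S1 = S2 = None
    else:
        S1 = _suffix_at(wX, B)
        S2 = _suffix_at(w[:, None] * s.XX2, B).reshape(len(B), p, p)
        grad += s.X[s.ev].sum(axis=0)

    if singles.any():
        A0 = S0[singles]
        ll -= float(np.log(A0).sum())
        if not ll_only:
            r1 = S1[singles] / A0[:, None]
            grad -= r1.sum(axis=0)
            info += (S2[singles] / A0[:, None, None]).sum(axis=0) - r1.T @ r1

    for g in tied:
        rows_g = s.ev[s.g_of_event == g]
        dg = len(rows_g)
        A0 = S0[g]
        B0 = w[rows_g].sum()
        if not ll_only:
            A1, A2 = S1[g], S2[g]
            B1 = wX[rows_g].sum(axis=0)
            B2 = wX[rows_g].T @ s.X[rows_g]
        for l in range(dg):
            f = l / dg
            phi0 = A0 - f * B0
            ll -= float(np.log(phi0))
            if not ll_only:
                phi1 = A1 - f * B1
                phi2 = A2 - f * B2
                r = phi1 / phi0
                grad -= r
                info += phi2 / phi0 - np.outer(r, r)
    return ll, grad, info


def _log_likelihood(beta: np.ndarray, strata: Sequence[_Stratum]) -> float:
    total = 0.0
    for s in strata:
        ll, _, _ = _stratum_ll_grad_info(beta, s, ll_only=True)
        total += ll
    return total


def _prepare(cohort: pd.DataFrame, outcome: str, predictors: Sequence[str],
             age_interactions: bool, sex: str | None):
    validate_cohort(cohort)
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome={outcome!r} not one of {OUTCOMES}")
    df = cohort if sex is None else cohort[cohort["sex"] == sex]
    if df.empty:
        raise ValueError("no subjects after sex filter")
    X, cols = design_matrix(df, predictors, age_interactions)
    d = (df["event"] == outcome).to_numpy()
    time = df["time"].to_numpy(dtype=float)
    regions = df["region"].to_numpy()
    return df, X, cols, d, time, regions


def fit_stratified_cox(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str] = PREDICTORS,
    age_interactions: bool = True,
    sex: str | None = None,
    horizon: float = 10.0,
    max_iter: int = 100,
    tol_grad: float = 1e-7,
    tol_ll: float = 1e-9,
) -> FitResult:
    """Fit one cause-specific submodel on a cohort table.

    All non-target first events (other CVD types, unspecified stroke, non-CVD
    death) censor the target outcome at their time.  Covariates with zero
    variance are dropped from the optimization, reported with beta 0 and an
    infinite standard error, and listed in ``zero_variance``.
    """
    df, X, cols, d, time, regions = _prepare(cohort, outcome, predictors,
                                             age_interactions, sex)
    n, p = X.shape
    if d.sum() == 0:
        raise FittingError(f"no {outcome} events in the fitting data")

    variances = X.var(axis=0)
    active = variances > 0.0
    zero_var = [c for c, a in zip(cols, active) if not a]
    Xa = X[:, active]
    pa = Xa.shape[1]

    strata = []
    for reg in pd.unique(regions):
        m = regions == reg
        if d[m].sum() == 0:
            warnings.warn(f"region {reg!r} has no {outcome} events; "
                          "it contributes no partial-likelihood terms")
        strata.append(_Stratum(time[m], d[m], Xa[m]))

    beta = np.zeros(pa)
    ll = _log_likelihood(beta, strata)
    grad_norm = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = np.zeros(pa)
        info = np.zeros((pa, pa))
        for s in strata:
            _, g, i = _stratum_ll_grad_info(beta, s)
            grad += g
            info += i
        grad_norm = float(np.max(np.abs(grad))) if pa else 0.0
        if pa == 0:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FittingError(
                f"singular information matrix at iteration {it} "
                f"(possible complete separation); |grad|={grad_norm:.3g}"
            ) from exc
        new_beta = beta + step
        new_ll = _log_likelihood(new_beta, strata)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = _log_likelihood(new_beta, strata)
            halvings += 1
        if not np.isfinite(new_ll):
            raise FittingError(f"log-likelihood not finite at iteration {it}")
        rel = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll = new_beta, new_ll
        if grad_norm < tol_grad and rel < tol_ll:
            converged = True
            break
        if np.max(np.abs(beta)) > 50:
            raise FittingError(
                f"coefficients diverging (max |beta| > 50) at iteration {it}; "
                "data may be completely separated"
            )
    if not converged:
        raise FittingError(
            f"no convergence after {max_iter} iterations; |grad|={grad_norm:.3g}"
        )

    se_active = np.full(pa, np.nan)
    if pa:
        try:
            cov = np.linalg.inv(info)
            se_active = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            warnings.warn("information matrix singular at solution; SEs unavailable")

    full_beta = np.zeros(p)
    full_beta[active] = beta
    full_se = np.full(p, np.inf)
    full_se[active] = se_active

    beta_main = {c: float(full_beta[j]) for j, c in enumerate(cols) if ":" not in c}
    beta_int = {c.split(":", 1)[1]: float(full_beta[j])
                for j, c in enumerate(cols) if ":" in c}
    ses = {c: float(full_se[j]) for j, c in enumerate(cols)}

    sex_label = sex if sex is not None else (
        df["sex"].iloc[0] if df["sex"].nunique() == 1 else "female")

    per_region = _baseline_survival(df, full_beta, cols, outcome, horizon,
                                    predictors, age_interactions)
    counts = _case_counts(df, outcome, horizon)
    pooled = pool_baseline_survival(per_region, counts)

    coeffs = CoefficientSet(
        outcome=outcome, sex=sex_label, beta_main=beta_main,
        beta_age_interaction=beta_int, s0_10=pooled,
    )
    return FitResult(
        coefficients=coeffs,
        standard_errors=ses,
        per_region_s0=per_region,
        case_counts=counts,
        n_subjects=n,
        n_events=int(d.sum()),
        log_likelihood=float(ll),
        n_iter=it,
        gradient_norm=grad_norm,
        converged=converged,
        zero_variance=zero_var,
        columns=list(cols),
        beta=full_beta,
    )


# ---------------------------------------------------------------------------
# baseline survival
# ---------------------------------------------------------------------------

def _case_counts(df: pd.DataFrame, outcome: str, horizon: float) -> dict:
    """Target-outcome events occurring by the horizon, per region."""
    hit = (df["event"] == outcome) & (df["time"] <= horizon)
    counts = hit.groupby(df["region"]).sum()
    return {reg: int(counts.get(reg, 0)) for reg in pd.unique(df["region"])}


def _baseline_survival(df: pd.DataFrame, beta: np.ndarray, cols: list[str],
                       outcome: str, horizon: float,
                       predictors: Sequence[str], age_interactions: bool) -> dict:
    """Per-region Breslow S0(horizon) at the centered covariate origin."""
    X, _ = design_matrix(df, predictors, age_interactions)
    eta = X @ beta
    d = (df["event"] == outcome).to_numpy()
    time = df["time"].to_numpy(dtype=float)
    regions = df["region"].to_numpy()
    out = {}
    for reg in pd.unique(regions):
        m = regions == reg
        out[reg] = _breslow_s0(time[m], d[m], eta[m], horizon)
    return out


def _breslow_s0(time: np.ndarray, d: np.ndarray, eta: np.ndarray,
                horizon: float) -> float:
    order = np.argsort(time, kind="stable")
    t, dd, w = time[order], d[order].astype(bool), np.exp(eta[order])
    if dd.sum() == 0:
        warnings.warn("region has no target events; baseline survival set to 1")
        return 1.0
    S0 = np.cumsum(w[::-1])[::-1]
    te = t[dd]
    keep = te <= horizon
    if not keep.any():
        warnings.warn("region has no target events before the horizon; "
                      "baseline survival set to 1")
        return 1.0
    rows = np.searchsorted(t, te[keep], side="left")
    H0 = float(np.sum(1.0 / S0[rows]))
    return float(np.exp(-H0))


def estimate_baseline_survival(cohort: pd.DataFrame, fit: FitResult, outcome: str,
                               horizon: float = 10.0,
                               sex: str | None = None) -> dict:
    """Per-region Breslow baseline survival at ``horizon`` under a fitted model."""
    validate_cohort(cohort)
    df = cohort if sex is None else cohort[cohort["sex"] == sex]
    preds = [c for c in fit.columns if ":" not in c]
    interactions = any(":" in c for c in fit.columns)
    return _baseline_survival(df, fit.beta, fit.columns, outcome, horizon,
                              preds, interactions)


def pool_baseline_survival(per_region: Mapping, case_counts: Mapping) -> float:
    """Case-weighted mean of per-region baseline survivals."""
    if set(per_region) != set(case_counts):
        raise ValueError("per_region and case_counts must share identical keys")
    total = float(sum(case_counts.values()))
    if total <= 0:
        raise ValueError("total case count is zero; pooled S0(10) undefined")
    if any(c < 0 for c in case_counts.values()):
        raise ValueError("case counts must be non-negative")
    return float(sum(per_region[r] * case_counts[r] for r in per_region) / total)


# ---------------------------------------------------------------------------
# internal-external cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Leave-one-region-out concordance, pooled by inverse variance."""

    pooled_c: float
    se: float
    ci: tuple[float, float]
    per_region: pd.DataFrame


def internal_external_cv(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str] = PREDICTORS,
    age_interactions: bool = True,
    sex: str | None = None,
    horizon: float = 10.0,
) -> CVResult:
    """Leave each region out, fit on the rest, validate Harrell C in it.

    Per-region C values are pooled with inverse-variance (fixed-effect)
    weights on the C scale; degenerate regions (fewer than two comparable
    pairs) are excluded with a warning.
    """
    validate_cohort(cohort)
    df = cohort if sex is None else cohort[cohort["sex"] == sex]
    regions = pd.unique(df["region"])
    if len(regions) < 3:
        raise ValueError("internal-external cross-validation needs >= 3 regions")
    rows = []
    for reg in regions:
        train = df[df["region"] != reg]
        test = df[df["region"] == reg]
        fit = fit_stratified_cox(train, outcome, predictors, age_interactions,
                                 horizon=horizon)
        risks = np.asarray(risk_from_lp(
            _lp_for(test, fit), fit.coefficients.s0_10))
        d = (test["event"] == outcome).to_numpy().astype(float)
        t = test["time"].to_numpy(dtype=float)
        try:
            res = harrell_c(risks, t, d)
        except ValueError:
            warnings.warn(f"region {reg!r} has <2 comparable pairs; excluded")
            continue
        rows.append({"region": reg, "c": res.c, "se": res.se,
                     "n": len(test), "n_pairs": res.n_comparable})
    if not rows:
        raise ValueError("no region produced a valid concordance estimate")
    table = pd.DataFrame(rows)
    se = np.maximum(table["se"].to_numpy(dtype=float), 1e-10)
    w = 1.0 / se**2
    pooled = float(np.sum(w * table["c"]) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    ci = (pooled - 1.959963984540054 * pooled_se, pooled + 1.959963984540054 * pooled_se)
    return CVResult(pooled_c=pooled, se=pooled_se, ci=ci, per_region=table)


def _lp_for(df: pd.DataFrame, fit: FitResult) -> np.ndarray:
    preds = [c for c in fit.columns if ":" not in c]
    interactions = any(":" in c for c in fit.columns)
    X, _ = design_matrix(df, preds, interactions)
    return X @ fit.beta


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def schoenfeld_residuals(cohort: pd.DataFrame, fit: FitResult, outcome: str,
                         sex: str | None = None) -> pd.DataFrame:
    """Unscaled Schoenfeld residuals x_i - xbar(risk set) at each event time.

    Intended for graphical proportional-hazards assessment (residual vs time);
    returned as a tidy frame with one row per event and one column per
    coefficient.
    """
    validate_cohort(cohort)
    df = cohort if sex is None else cohort[cohort["sex"] == sex]
    preds = [c for c in fit.columns if ":" not in c]
    interactions = any(":" in c for c in fit.columns)
    X, cols = design_matrix(df, preds, interactions)
    eta = X @ fit.beta
    d = (df["event"] == outcome).to_numpy()
    time = df["time"].to_numpy(dtype=float)
    regions = df["region"].to_numpy()
    frames = []
    for reg in pd.unique(regions):
        m = regions == reg
        order = np.argsort(time[m], kind="stable")
        t, dd = time[m][order], d[m][order]
        Xs = X[m][order]
        w = np.exp(eta[m][order])
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
        ev = np.flatnonzero(dd)
        rows = np.searchsorted(t, t[ev], side="left")
        resid = Xs[ev] - S1[rows] / S0[rows, None]
        fr = pd.DataFrame(resid, columns=cols)
        fr.insert(0, "time", t[ev])
        fr.insert(0, "region", reg)
        frames.append(fr)
    return pd.concat(frames, ignore_index=True).sort_values("time", ignore_index=True)


def independence_diagnostic(cohort: pd.DataFrame, family,
                            horizon: float = 10.0) -> dict:
    """Compare mean combined predicted risk to an Aalen–Johansen any-CVD risk.

    The conditional-probability combination assumes the three cause-specific
    risks act independently.  This diagnostic reports (not enforces) how the
    mean combined prediction compares with a nonparametric any-CVD cumulative
    incidence that treats non-CVD death as a competing risk.
    """
    from lifelines import AalenJohansenFitter
    from .model_core import predict_risk_frame

    validate_cohort(cohort)
    df = cohort[cohort["sex"] == family.sex]
    risks = predict_risk_frame(df, family)
    cvd = df["event"].isin(["IHD", "IS", "HS", "unspecified_stroke"])
    code = np.where(cvd, 1, np.where(df["event"] == "death_other", 2, 0))
    ajf = AalenJohansenFitter(calculate_variance=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ajf.fit(df["time"].to_numpy(dtype=float), code, event_of_interest=1)
    ci = ajf.cumulative_density_
    at_h = float(ci[ci.index <= horizon].iloc[-1, 0]) if len(ci) else 0.0
    return {
        "mean_predicted_cvd_risk": float(risks["risk_cvd"].mean()),
        "aalen_johansen_any_cvd_risk": at_h,
        "n": int(len(df)),
    }
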