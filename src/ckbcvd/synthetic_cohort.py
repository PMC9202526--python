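"""Synthetic multi-region cohort generator.

Generates cohorts with the covariate structure of the derivation population
(age uniform over 30–79; SBP/DBP bivariate normal around the published
medians; waist circumference normal; binary predictors at the published
prevalences) and cause-specific event times driven by the packaged
log-linear predictors.

Each subject carries constant (exponential) cause-specific hazards

    lambda_k = lambda0_k * m_{k,region} * exp(LP_k(x)),

where ``lambda0_k = -ln(S0_k(10)) / 10`` reproduces the published baseline
10-year survival at the covariate origin when the region multiplier ``m`` is
1, and the multipliers (default spread over [0.5, 2]) create the strong
regional variation in absolute risk that motivates recalibration.  Small
constant hazards for unspecified stroke and non-CVD death act as additional
competing causes.  The first event across causes, administrative censoring
at 10–13 years, and <1% random loss to follow-up determine each subject's
(time, event) pair.  Constant hazards keep every cumulative incidence in
closed form for testing; a Weibull shape parameter is exposed for robustness
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .model_core import (
    OUTCOMES,
    SEXES,
    ModelFamily,
    linear_predictor_frame,
    load_family,
)

#: age bands used for recalibration summaries (5-year bands over 30-79)
AGE_BAND_EDGES = np.arange(30, 85, 5)


@dataclass(frozen=True)
class CovariateModel:
    """Per-sex covariate distribution (natural units)."""

    sbp_mean: float
    dbp_mean: float
    sbp_sd: float = 20.0
    dbp_sd: float = 11.0
    bp_corr: float = 0.7
    waist_mean: float = 80.0
    waist_sd: float = 10.0
    prev_daily_smoker: float = 0.0
    prev_bp_treatment: float = 0.0
    prev_diabetes: float = 0.0

    def __post_init__(self) -> None:
        for name in ("prev_daily_smoker", "prev_bp_treatment", "prev_diabetes"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        if self.dbp_mean >= self.sbp_mean:
            raise ValueError("mean DBP must be below mean SBP")
        if not (-1.0 < self.bp_corr < 1.0):
            raise ValueError("bp_corr must lie in (-1, 1)")


#: defaults reproduce the published baseline characteristics table
DEFAULT_COVARIATES: dict[str, CovariateModel] = {
    "female": CovariateModel(
        sbp_mean=126.0, dbp_mean=76.0, waist_mean=78.2, waist_sd=9.6,
        prev_daily_smoker=0.020, prev_bp_treatment=0.118, prev_diabetes=0.029,
    ),
    "male": CovariateModel(
        sbp_mean=129.5, dbp_mean=78.5, waist_mean=81.3, waist_sd=10.4,
        prev_daily_smoker=0.571, prev_bp_treatment=0.102, prev_diabetes=0.025,
    ),
}


def default_multipliers(n_regions: int) -> dict[str, np.ndarray]:
    """Region baseline-hazard multipliers per outcome, spread over [0.5, 2].

    The grid is rotated by one position per outcome so that no two outcomes
    share an identical regional profile.
    """
    base = np.geomspace(0.5, 2.0, n_regions)
    return {o: np.roll(base, k) for k, o in enumerate(OUTCOMES)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort."""

    seed: int
    n_per_region: int = 20000
    n_regions: int = 10
    female_fraction: float = 0.59
    covariates: Mapping[str, CovariateModel] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES))
    multipliers: Mapping[str, np.ndarray] | None = None
    families: Mapping[str, ModelFamily] | None = None
    admin_censor_years: tuple[float, float] = (10.0, 13.0)
    loss_fraction: float = 0.008
    death_other_rate: float = 0.004
    unspecified_stroke_fraction: float = 0.013
    weibull_shape: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_region <= 0 or self.n_regions <= 0:
            raise ValueError("n_per_region and n_regions must be positive")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must lie in [0, 1]")
        if not (0.0 <= self.loss_fraction < 0.05):
            raise ValueError("loss_fraction must lie in [0, 0.05)")
        lo, hi = self.admin_censor_years
        if not (0 < lo <= hi):
            raise ValueError("administrative censoring window must satisfy 0 < lo <= hi")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        if self.death_other_rate < 0 or self.unspecified_stroke_fraction < 0:
            raise ValueError("competing-cause rates must be non-negative")
        mult = self.multipliers
        if mult is None:
            mult = default_multipliers(self.n_regions)
        mult = {o: np.asarray(m, dtype=float) for o, m in mult.items()}
        for o, m in mult.items():
            if o not in OUTCOMES:
                raise ValueError(f"unknown outcome {o!r} in multipliers")
            if len(m) != self.n_regions:
                raise ValueError(f"multipliers for {o} must have length {self.n_regions}")
            if (m < 0).any():
                raise ValueError("multipliers must be non-negative")
        object.__setattr__(self, "multipliers", mult)

    def resolved_families(self) -> dict[str, ModelFamily]:
        if self.families is not None:
            return dict(self.families)
        return {sex: load_family(sex) for sex in SEXES}


def _draw_covariates(rng: np.random.Generator, n: int, sex: str,
                     cov: CovariateModel) -> pd.DataFrame:
    age = rng.uniform(30.0, 79.0, n)

    mean = np.array([cov.sbp_mean, cov.dbp_mean])
    c = cov.bp_corr * cov.sbp_sd * cov.dbp_sd
    covmat = np.array([[cov.sbp_sd ** 2, c], [c, cov.dbp_sd ** 2]])
    bp = rng.multivariate_normal(mean, covmat, size=n)
    # redraw physiologically impossible pairs (SBP < DBP or out of range)
    for _ in range(100):
        bad = (bp[:, 0] < bp[:, 1]) | (bp[:, 0] < 60) | (bp[:, 0] > 280) \
            | (bp[:, 1] < 30) | (bp[:, 1] > 200)
        if not bad.any():
            break
        bp[bad] = rng.multivariate_normal(mean, covmat, size=int(bad.sum()))

    waist = rng.normal(cov.waist_mean, cov.waist_sd, n)
    for _ in range(100):
        bad = (waist < 40) | (waist > 180)
        if not bad.any():
            break
        waist[bad] = rng.normal(cov.waist_mean, cov.waist_sd, int(bad.sum()))

    return pd.DataFrame({
        "sex": sex,
        "age": age,
        "sbp": bp[:, 0],
        "dbp": bp[:, 1],
        "bp_treatment": (rng.random(n) < cov.prev_bp_treatment).astype(int),
        "daily_smoker": (rng.random(n) < cov.prev_daily_smoker).astype(int),
        "diabetes": (rng.random(n) < cov.prev_diabetes).astype(int),
        "waist": waist,
    })


def _draw_times(rng: np.random.Generator, hazard: np.ndarray,
                shape: float) -> np.ndarray:
    """Event times with survival exp(-hazard * t^shape); inf where hazard 0."""
    e = rng.exponential(1.0, len(hazard))
    with np.errstate(divide="ignore"):
        t = np.where(hazard > 0, (e / np.where(hazard > 0, hazard, 1.0)), np.inf)
    if shape != 1.0:
        t = np.where(np.isfinite(t), t ** (1.0 / shape), t)
    return t


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a multi-region cohort table; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    families = config.resolved_families()
    n_female = int(round(config.n_per_region * config.female_fraction))
    frames = []
    next_id = 1
    for r in range(config.n_regions):
        region = r + 1
        for sex, n in (("female", n_female),
                       ("male", config.n_per_region - n_female)):
            if n == 0:
                continue
            df = _draw_covariates(rng, n, sex, config.covariates[sex])
            family = families[sex]

            cause_hazards = {}
            for outcome in OUTCOMES:
                coeffs = family.submodels[outcome]
                lam0 = -np.log(coeffs.s0_10) / 10.0
                mult = float(config.multipliers[outcome][r])
                lp = linear_predictor_frame(df, coeffs)
                cause_hazards[outcome] = lam0 * mult * np.exp(lp)
            cause_hazards["unspecified_stroke"] = (
                config.unspecified_stroke_fraction
                * (cause_hazards["IS"] + cause_hazards["HS"]))
            cause_hazards["death_other"] = np.full(n, config.death_other_rate)

            total = sum(cause_hazards.values())
            p10 = 1.0 - np.exp(-10.0 * total)
            if (p10 > 0.99).any():
                warnings.warn(
                    f"{int((p10 > 0.99).sum())} subjects in region {region} "
                    f"({sex}) have >99% 10-year event probability"
                )

            causes = list(cause_hazards)
            times = np.column_stack([
                _draw_times(rng, cause_hazards[c], config.weibull_shape)
                for c in causes
            ])
            lo, hi = config.admin_censor_years
            censor = rng.uniform(lo, hi, n)
            lost = rng.random(n) < config.loss_fraction
            loss_time = rng.uniform(0.0, censor)
            censor = np.where(lost, np.minimum(censor, loss_time), censor)

            first_cause = np.argmin(times, axis=1)
            first_time = times[np.arange(n), first_cause]
            is_event = first_time <= censor
            time = np.where(is_event, first_time, censor)
            event = np.where(is_event,
                             np.asarray(causes, dtype=object)[first_cause],
                             "none")

            df.insert(0, "region", region)
            df.insert(0, "id", np.arange(next_id, next_id + n))
            df["time"] = np.maximum(time, 1e-8)
            df["event"] = event
            next_id += n
            frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    return cohort[["id", "region", "sex", "age", "sbp", "dbp", "bp_treatment",
                   "daily_smoker", "diabetes", "waist", "time", "event"]]


def age_band_label(age: float) -> str:
    lo = int(np.clip((age - 30) // 5, 0, len(AGE_BAND_EDGES) - 2) * 5 + 30)
    return f"{lo}-{lo + 4}"


def make_recalibration_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cross-sectional summary consumed by practical recalibration.

    Per region x sex x 5-year age band: population share, mean of the seven
    predictors (binaries as prevalences) and annual incidence per outcome
    (first events of that type divided by total person-years in the band).
    """
    from .derivation import validate_cohort

    validate_cohort(cohort)
    df = cohort.copy()
    df["age_group"] = pd.cut(
        df["age"], AGE_BAND_EDGES, right=False,
        labels=[f"{lo}-{lo + 4}" for lo in AGE_BAND_EDGES[:-1]],
    ).astype(str)
    rows = []
    for (region, sex), block in df.groupby(["region", "sex"], sort=True):
        n_total = len(block)
        for band, grp in block.groupby("age_group", sort=True):
            if grp.empty:
                continue
            py = float(grp["time"].sum())
            row = {
                "region": region,
                "sex": sex,
                "age_group": band,
                "population_share": len(grp) / n_total,
                "age": float(grp["age"].mean()),
                "sbp": float(grp["sbp"].mean()),
                "dbp": float(grp["dbp"].mean()),
                "bp_treatment": float(grp["bp_treatment"].mean()),
                "daily_smoker": float(grp["daily_smoker"].mean()),
                "diabetes": float(grp["diabetes"].mean()),
                "waist": float(grp["waist"].mean()),
            }
            for outcome, col in (("IHD", "incidence_ihd"), ("IS", "incidence_is"),
                                 ("HS", "incidence_hs")):
                row[col] = float((grp["event"] == outcome).sum() / py) if py > 0 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def competing_exponential_incidence(cause_hazard: float, total_hazard: float,
                                    t: float) -> float:
    """Closed-form cumulative incidence of one cause among competing
    constant-hazard causes: (lam_k / lam_tot) * (1 - exp(-lam_tot * t))."""
    if total_hazard == 0:
        return 0.0
    return cause_hazard / total_hazard * (1.0 - np.exp(-total_hazard * t))
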