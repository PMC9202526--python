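"""Regional recalibration of a fitted model family.

Recalibration adapts a model to a target region by replacing each submodel's
baseline survival while leaving every regression coefficient untouched.  Two
methods are provided:

* **practical** — uses only cross-sectional summaries (age-group mean
  risk-factor levels and annual incidence per outcome).  For each outcome the
  expected 10-year cumulative hazard at each age group's mean profile,
  ``Hhat_g = exp(LP_g) * (-ln S0(10))``, is compared with the observed
  ``H_g = 10 * lambda_g`` from the annual incidence, and the population-share
  weighted ratio ``c = sum w_g H_g / sum w_g Hhat_g`` rescales the baseline
  on the cumulative-hazard scale: ``S0_new = S0 ** c``.  This is the standard
  flexible recalibration mechanism for risk charts built from summary data.
* **ideal** — assumes the region's observed 10-year risk (Kaplan–Meier, with
  competing events censored) is available and solves for the baseline
  survival at which the region's mean predicted risk equals it.

Because both methods apply a strictly monotone transform to each submodel's
risk, within-region discrimination (Harrell C) is unchanged by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import (
    OUTCOMES,
    ConfigurationError,
    ModelFamily,
    linear_predictor_frame,
    linear_predictor_from_values,
    predict_risk_frame,
)
from .evaluation import km_observed_risk

#: recalibration-table columns holding age-group mean predictor levels
TABLE_PREDICTORS = ("age", "sbp", "dbp", "bp_treatment", "daily_smoker",
                    "diabetes", "waist")
TABLE_COLUMNS = ("region", "sex", "age_group", "population_share",
                 *TABLE_PREDICTORS,
                 "incidence_ihd", "incidence_is", "incidence_hs")
_INCIDENCE_COL = {"IHD": "incidence_ihd", "IS": "incidence_is", "HS": "incidence_hs"}


def validate_recalibration_table(table: pd.DataFrame) -> None:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"recalibration table missing columns: {sorted(missing)}")
    if (table[list(_INCIDENCE_COL.values())] < 0).any().any():
        raise ValueError("annual incidences must be non-negative")
    shares = table.groupby(["region", "sex"])["population_share"].sum()
    bad = shares[(shares - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(
            f"population shares must sum to 1 within region x sex; got {bad.to_dict()}"
        )


@dataclass(frozen=True)
class RecalibratedFamily:
    """A model family with per-region baseline-survival overrides.

    Betas are identical to the parent family; only ``S0(10)`` differs by
    region and outcome.  ``correction`` records the cumulative-hazard scale
    factor applied per region and outcome (``S0_new = S0 ** c``).
    """

    family: ModelFamily
    s0_overrides: Mapping[Any, Mapping[str, float]]
    provenance: str  # "practical" | "ideal"
    correction: Mapping[Any, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.provenance not in ("practical", "ideal"):
            raise ConfigurationError(f"unknown provenance {self.provenance!r}")
        for reg, by_outcome in self.s0_overrides.items():
            for outcome, s0 in by_outcome.items():
                if outcome not in OUTCOMES:
                    raise ConfigurationError(f"unknown outcome {outcome!r} in overrides")
                if not (0.0 < s0 <= 1.0):
                    raise ConfigurationError(
                        f"override s0={s0!r} for region {reg!r}/{outcome} outside (0, 1]"
                    )
        object.__setattr__(self, "s0_overrides",
                           {r: dict(v) for r, v in self.s0_overrides.items()})
        object.__setattr__(self, "correction",
                           {r: dict(v) for r, v in self.correction.items()})

    @property
    def sex(self) -> str:
        return self.family.sex

    def risk_frame(self, df: pd.DataFrame, region_col: str = "region") -> pd.DataFrame:
        """Per-row risks using each row's regional baseline override."""
        return predict_risk_frame(df, self.family, s0_overrides=self.s0_overrides,
                                  region_col=region_col)

    def to_dict(self) -> dict:
        doc = self.family.to_dict()
        doc["recalibration"] = {
            "provenance": self.provenance,
            "s0_overrides": {str(r): {o: float(s) for o, s in v.items()}
                             for r, v in self.s0_overrides.items()},
            "correction": {str(r): {o: float(c) for o, c in v.items()}
                           for r, v in self.correction.items()},
        }
        return doc


def merge_recalibrations(parts: list[RecalibratedFamily]) -> RecalibratedFamily:
    """Combine single-region recalibrations into one multi-region family."""
    if not parts:
        raise ValueError("no recalibrations to merge")
    base = parts[0]
    overrides: dict[Any, dict[str, float]] = {}
    corrections: dict[Any, dict[str, float]] = {}
    for part in parts:
        if part.provenance != base.provenance or part.family is not base.family:
            if part.family.to_dict() != base.family.to_dict():
                raise ConfigurationError("recalibrations derive from different families")
        overrides.update(part.s0_overrides)
        corrections.update(part.correction)
    return RecalibratedFamily(family=base.family, s0_overrides=overrides,
                              provenance=base.provenance, correction=corrections)


# ---------------------------------------------------------------------------
# practical recalibration (cross-sectional summary data)
# ---------------------------------------------------------------------------

def practical_recalibrate(family: ModelFamily, table: pd.DataFrame, region,
                          incidence_kind: str = "rate") -> RecalibratedFamily:
    """Recalibrate one region from age-group means and annual incidences.

    ``incidence_kind`` selects how the observed 10-year cumulative hazard is
    formed from the annual incidence column: ``"rate"`` (events per
    person-year; H = 10 * lambda, the default) or ``"annual_risk"``
    (H = -10 * ln(1 - q)).
    """
    validate_recalibration_table(table)
    if incidence_kind not in ("rate", "annual_risk"):
        raise ValueError(f"incidence_kind={incidence_kind!r}")
    rows = table[(table["region"] == region) & (table["sex"] == family.sex)]
    if rows.empty:
        raise ValueError(f"recalibration table has no rows for region {region!r} "
                         f"and sex {family.sex!r}")
    overrides: dict[str, float] = {}
    corrections: dict[str, float] = {}
    w = rows["population_share"].to_numpy(dtype=float)
    for outcome in OUTCOMES:
        coeffs = family.submodels[outcome]
        lps = np.array([
            linear_predictor_from_values(
                {p: row[p] for p in coeffs.beta_main}, coeffs)
            for _, row in rows.iterrows()
        ])
        h_hat = np.exp(lps) * (-np.log(coeffs.s0_10))
        lam = rows[_INCIDENCE_COL[outcome]].to_numpy(dtype=float)
        if incidence_kind == "rate":
            h_obs = 10.0 * lam
        else:
            h_obs = -10.0 * np.log1p(-lam)
        denom = float(np.sum(w * h_hat))
        if denom <= 0:
            raise ValueError(
                f"predicted cumulative hazard is zero for {outcome}; "
                "cannot form a correction factor"
            )
        c = float(np.sum(w * h_obs)) / denom
        corrections[outcome] = c
        overrides[outcome] = float(coeffs.s0_10 ** c)
    return RecalibratedFamily(
        family=family,
        s0_overrides={region: overrides},
        provenance="practical",
        correction={region: corrections},
    )


# ---------------------------------------------------------------------------
# ideal recalibration (observed 10-year risk)
# ---------------------------------------------------------------------------

def solve_s0_for_mean_risk(lps: np.ndarray, target_risk: float,
                           tol: float = 1e-10) -> float:
    """Baseline survival at which mean(1 - s0^exp(LP)) equals ``target_risk``.

    The mean predicted risk is strictly decreasing in s0, so a single root
    exists on (0, 1) whenever 0 < target < 1; solved by Brent's method.
    """
    if target_risk <= 0.0:
        warnings.warn("observed risk is zero; baseline survival set to 1")
        return 1.0
    if target_risk >= 1.0:
        raise ValueError("observed risk must be < 1 for a root in (0, 1)")
    e = np.exp(np.asarray(lps, dtype=float))

    def gap(s0: float) -> float:
        return float(np.mean(1.0 - s0 ** e)) - target_risk

    lo, hi = 1e-300, 1.0 - 1e-16
    if gap(hi) > 0 or gap(lo) < 0:
        raise ValueError("no baseline survival in (0, 1) matches the observed risk")
    root = float(brentq(gap, lo, hi, xtol=1e-16, rtol=8.9e-16))
    if abs(gap(root)) > tol:
        raise ValueError(
            f"root finding left a mean-risk gap of {gap(root):.3g} (> {tol})"
        )
    return root


def ideal_recalibrate(family: ModelFamily, cohort: pd.DataFrame, region,
                      horizon: float = 10.0) -> RecalibratedFamily:
    """Recalibrate one region to its observed 10-year risks.

    The observed risk per outcome is the Kaplan–Meier estimate at the horizon
    in the region, with competing first events censored — the same
    cause-specific convention used in model derivation.
    """
    from .derivation import validate_cohort

    validate_cohort(cohort)
    df = cohort[(cohort["region"] == region) & (cohort["sex"] == family.sex)]
    if df.empty:
        raise ValueError(f"no subjects in region {region!r} for sex {family.sex!r}")
    t = df["time"].to_numpy(dtype=float)
    overrides: dict[str, float] = {}
    corrections: dict[str, float] = {}
    for outcome in OUTCOMES:
        coeffs = family.submodels[outcome]
        lps = linear_predictor_frame(df, coeffs)
        d = (df["event"] == outcome).to_numpy(dtype=float)
        observed = km_observed_risk(t, d, horizon)
        s0_new = solve_s0_for_mean_risk(lps, observed)
        overrides[outcome] = s0_new
        corrections[outcome] = float(np.log(s0_new) / np.log(coeffs.s0_10))
    return RecalibratedFamily(
        family=family,
        s0_overrides={region: overrides},
        provenance="ideal",
        correction={region: corrections},
    )
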