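"""Sex-specific 10-year cardiovascular risk engine.

The model family consists of three cause-specific Cox submodels per sex —
ischemic heart disease (IHD), ischemic stroke (IS) and hemorrhagic stroke
(HS) — each of the form

    risk_k(x) = 1 - S0_k(10) ** exp(LP_k(x))

where ``LP_k`` is a linear predictor over seven predictors (age, systolic
and diastolic blood pressure, use of blood-pressure-lowering treatment,
current daily smoking, self-reported diabetes, waist circumference) plus
age-by-predictor interaction terms, and ``S0_k(10)`` is the baseline
survival probability at 10 years for the reference (centered) profile.

All continuous predictors enter linearly in *model units*: age per 5 years
centered at 55, SBP and DBP per 10 mm Hg centered at 120 / 80 mm Hg, waist
circumference per 10 cm centered at 80 cm; binary predictors are coded 0/1
and centered at 0 (absent).  The age-interaction coefficient for predictor
``p`` multiplies ``u_age * u_p`` where ``u_age = (age - 55) / 5`` — i.e. it
is a log-hazard-ratio per model unit of ``p`` per 5 years of age.

Total CVD risk combines the three cause-specific risks under the
conditional-probability (independence) identity

    risk_CVD = 1 - (1 - risk_IHD)(1 - risk_IS)(1 - risk_HS).

The packaged coefficient sets store log-HRs derived from the published
hazard ratios (printed to 2 decimals); the exact regression coefficients
were never released, so parameter-recovery checks use tolerances rather
than equality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

OUTCOMES = ("IHD", "IS", "HS")
SEXES = ("female", "male")
PREDICTORS = ("age", "sbp", "dbp", "bp_treatment", "daily_smoker", "diabetes", "waist")

#: centering constants in natural units
CENTERS: dict[str, float] = {
    "age": 55.0,
    "sbp": 120.0,
    "dbp": 80.0,
    "waist": 80.0,
    "bp_treatment": 0.0,
    "daily_smoker": 0.0,
    "diabetes": 0.0,
}

#: natural units per model unit (age per 5 y; pressures per 10 mm Hg; waist per 10 cm)
SCALES: dict[str, float] = {
    "age": 5.0,
    "sbp": 10.0,
    "dbp": 10.0,
    "waist": 10.0,
    "bp_treatment": 1.0,
    "daily_smoker": 1.0,
    "diabetes": 1.0,
}

#: admissible ranges for continuous predictors (natural units)
RANGES: dict[str, tuple[float, float]] = {
    "age": (30.0, 79.0),
    "sbp": (60.0, 280.0),
    "dbp": (30.0, 200.0),
    "waist": (40.0, 180.0),
}

RISK_HORIZON_YEARS = 10.0


class ValidationError(ValueError):
    """An input value violates a documented invariant; names the field."""


class ContractError(ValueError):
    """A call violates a precondition (e.g. sex mismatch between inputs)."""


class ConfigurationError(ValueError):
    """A model object is incomplete or internally inconsistent."""


def _check_range(name: str, value: float) -> None:
    lo, hi = RANGES[name]
    if not (lo <= value <= hi):
        raise ValidationError(f"{name}={value!r} outside admissible range [{lo}, {hi}]")


@dataclass(frozen=True)
class RiskProfile:
    """One individual's predictor values in natural units."""

    sex: str
    age: float
    sbp: float
    dbp: float
    bp_treatment: bool
    daily_smoker: bool
    diabetes: bool
    waist: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex={self.sex!r} not one of {SEXES}")
        for name in ("age", "sbp", "dbp", "waist"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValidationError(f"{name}={value!r} is not finite")
            _check_range(name, float(value))
        if self.sbp < self.dbp:
            raise ValidationError(
                f"sbp={self.sbp!r} must be >= dbp={self.dbp!r}"
            )
        for name in ("bp_treatment", "daily_smoker", "diabetes"):
            value = getattr(self, name)
            if value not in (0, 1, True, False):
                raise ValidationError(f"{name}={value!r} must be boolean (or 0/1)")

    def values(self) -> dict[str, float]:
        """Predictor values as a plain mapping (binaries as 0.0/1.0)."""
        return {
            "age": float(self.age),
            "sbp": float(self.sbp),
            "dbp": float(self.dbp),
            "bp_treatment": float(bool(self.bp_treatment)),
            "daily_smoker": float(bool(self.daily_smoker)),
            "diabetes": float(bool(self.diabetes)),
            "waist": float(self.waist),
        }


def reference_profile(sex: str) -> RiskProfile:
    """The centered reference individual (every predictor at its centering constant)."""
    return RiskProfile(
        sex=sex, age=55.0, sbp=120.0, dbp=80.0,
        bp_treatment=False, daily_smoker=False, diabetes=False, waist=80.0,
    )


def centered_units(values: Mapping[str, float]) -> dict[str, float]:
    """Convert natural-unit predictor values into centered model units."""
    return {
        name: (float(values[name]) - CENTERS.get(name, 0.0)) / SCALES.get(name, 1.0)
        for name in values
    }


@dataclass(frozen=True)
class CoefficientSet:
    """Coefficients of one cause-specific submodel.

    ``beta_main`` maps predictor -> log-HR per model unit; ``beta_age_interaction``
    maps predictor -> log-HR per model unit per 5 years of age; ``s0_10`` is the
    10-year baseline survival at the centered origin.
    """

    outcome: str
    sex: str
    beta_main: Mapping[str, float]
    beta_age_interaction: Mapping[str, float]
    s0_10: float
    centers: Mapping[str, float] = field(default_factory=lambda: dict(CENTERS))

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"outcome={self.outcome!r} not one of {OUTCOMES}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex={self.sex!r} not one of {SEXES}")
        if not (0.0 < self.s0_10 < 1.0):
            raise ValidationError(f"s0_10={self.s0_10!r} must lie in (0, 1)")
        extra = set(self.beta_age_interaction) - set(self.beta_main)
        if extra - {"age"}:
            raise ValidationError(
                f"age-interaction terms for predictors absent from beta_main: {sorted(extra)}"
            )
        if "age" in self.beta_age_interaction:
            raise ValidationError("the age main effect cannot interact with itself")
        object.__setattr__(self, "beta_main", dict(self.beta_main))
        object.__setattr__(self, "beta_age_interaction", dict(self.beta_age_interaction))
        object.__setattr__(self, "centers", dict(self.centers))

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.beta_main)

    def hazard_ratios(self) -> dict[str, dict[str, float]]:
        """exp(beta) for audit against the published table."""
        return {
            "main": {p: math.exp(b) for p, b in self.beta_main.items()},
            "age_interaction": {p: math.exp(b) for p, b in self.beta_age_interaction.items()},
        }


def linear_predictor_from_values(values: Mapping[str, float], coeffs: CoefficientSet) -> float:
    """Linear predictor from raw predictor values (no profile validation).

    Accepts fractional values for binary predictors — practical recalibration
    evaluates the LP at age-group *mean* risk-factor levels, where e.g. smoking
    enters as a prevalence.
    """
    u = centered_units({p: values[p] for p in coeffs.beta_main})
    lp = sum(coeffs.beta_main[p] * u[p] for p in coeffs.beta_main)
    u_age = u.get("age", 0.0)
    lp += sum(coeffs.beta_age_interaction[p] * u_age * u[p] for p in coeffs.beta_age_interaction)
    return lp


def linear_predictor(profile: RiskProfile, coeffs: CoefficientSet) -> float:
    """Centered linear predictor LP for one individual under one submodel."""
    if profile.sex != coeffs.sex:
        raise ContractError(
            f"profile sex {profile.sex!r} does not match coefficient sex {coeffs.sex!r}"
        )
    return linear_predictor_from_values(profile.values(), coeffs)


def risk_from_lp(lp: float | np.ndarray, s0_10: float) -> float | np.ndarray:
    """10-year absolute risk 1 - S0(10)^exp(LP)."""
    return 1.0 - np.power(s0_10, np.exp(lp))


def predict_submodel_risk(profile: RiskProfile, coeffs: CoefficientSet) -> float:
    """10-year absolute risk of one outcome for one individual."""
    return float(risk_from_lp(linear_predictor(profile, coeffs), coeffs.s0_10))


def combine_risks(risk_ihd: float, risk_is: float, risk_hs: float) -> float:
    """Conditional-probability combination of the three cause-specific risks."""
    return 1.0 - (1.0 - risk_ihd) * (1.0 - risk_is) * (1.0 - risk_hs)


@dataclass(frozen=True)
class RiskResult:
    """Per-outcome and combined 10-year risks for one individual."""

    risk_ihd: float
    risk_is: float
    risk_hs: float
    risk_cvd: float
    linear_predictors: Mapping[str, float]


@dataclass(frozen=True)
class ModelFamily:
    """The three cause-specific submodels for one sex."""

    sex: str
    submodels: Mapping[str, CoefficientSet]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(OUTCOMES) - set(self.submodels)
        if missing:
            raise ConfigurationError(f"missing submodels for outcomes: {sorted(missing)}")
        extra = set(self.submodels) - set(OUTCOMES)
        if extra:
            raise ConfigurationError(f"unknown outcomes: {sorted(extra)}")
        for outcome, coeffs in self.submodels.items():
            if coeffs.outcome != outcome:
                raise ConfigurationError(
                    f"submodel keyed {outcome!r} has outcome {coeffs.outcome!r}"
                )
            if coeffs.sex != self.sex:
                raise ConfigurationError(
                    f"submodel {outcome} has sex {coeffs.sex!r}, family is {self.sex!r}"
                )
        object.__setattr__(self, "submodels", dict(self.submodels))
        object.__setattr__(self, "metadata", dict(self.metadata))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "schema_version": "1",
            "sex": self.sex,
            "metadata": dict(self.metadata),
            "submodels": {},
        }
        for outcome in OUTCOMES:
            coeffs = self.submodels[outcome]
            preds: dict[str, Any] = {}
            for p, b in coeffs.beta_main.items():
                entry: dict[str, Any] = {
                    "log_hr_main": b,
                    "hr_main": math.exp(b),
                    "center": coeffs.centers.get(p, CENTERS.get(p, 0.0)),
                }
                if p in coeffs.beta_age_interaction:
                    bi = coeffs.beta_age_interaction[p]
                    entry["log_hr_age_interaction"] = bi
                    entry["hr_age_interaction"] = math.exp(bi)
                preds[p] = entry
            doc["submodels"][outcome] = {
                "outcome": outcome,
                "s0_10": coeffs.s0_10,
                "predictors": preds,
            }
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "ModelFamily":
        sex = doc["sex"]
        submodels = {}
        for outcome, block in doc["submodels"].items():
            beta_main, beta_int, centers = {}, {}, {}
            for p, entry in block["predictors"].items():
                beta_main[p] = float(entry["log_hr_main"])
                centers[p] = float(entry.get("center", CENTERS.get(p, 0.0)))
                if "log_hr_age_interaction" in entry:
                    beta_int[p] = float(entry["log_hr_age_interaction"])
            submodels[outcome] = CoefficientSet(
                outcome=outcome, sex=sex, beta_main=beta_main,
                beta_age_interaction=beta_int, s0_10=float(block["s0_10"]),
                centers=centers,
            )
        return cls(sex=sex, submodels=submodels, metadata=dict(doc.get("metadata", {})))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ModelFamily":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_family(sex: str) -> ModelFamily:
    """Load the packaged published coefficient set for one sex."""
    if sex not in SEXES:
        raise ValidationError(f"sex={sex!r} not one of {SEXES}")
    ref = resources.files("ckbcvd.data").joinpath(f"coefficients_{sex}.json")
    return ModelFamily.from_dict(json.loads(ref.read_text()))


def predict_total_cvd(profile: RiskProfile, family: ModelFamily) -> RiskResult:
    """Cause-specific and combined 10-year risks for one individual."""
    if profile.sex != family.sex:
        raise ContractError(
            f"profile sex {profile.sex!r} does not match family sex {family.sex!r}"
        )
    lps = {o: linear_predictor(profile, family.submodels[o]) for o in OUTCOMES}
    risks = {o: float(risk_from_lp(lps[o], family.submodels[o].s0_10)) for o in OUTCOMES}
    return RiskResult(
        risk_ihd=risks["IHD"],
        risk_is=risks["IS"],
        risk_hs=risks["HS"],
        risk_cvd=combine_risks(risks["IHD"], risks["IS"], risks["HS"]),
        linear_predictors=lps,
    )


# ---------------------------------------------------------------------------
# vectorized interface over cohort DataFrames
# ---------------------------------------------------------------------------

def design_columns(predictors: Iterable[str] = PREDICTORS,
                   age_interactions: bool = True) -> list[str]:
    """Column names of the centered design matrix; interactions as ``age:p``."""
    predictors = list(predictors)
    cols = list(predictors)
    if age_interactions and "age" in predictors:
        cols += [f"age:{p}" for p in predictors if p != "age"]
    return cols


def design_matrix(df: pd.DataFrame, predictors: Iterable[str] = PREDICTORS,
                  age_interactions: bool = True) -> tuple[np.ndarray, list[str]]:
    """Centered model-unit design matrix for a cohort table.

    Columns not in the standard predictor set are passed through unscaled
    (center 0, scale 1), which supports fitting toy models on arbitrary
    covariates.
    """
    predictors = list(predictors)
    units = {}
    for p in predictors:
        v = df[p].to_numpy(dtype=float)
        units[p] = (v - CENTERS.get(p, 0.0)) / SCALES.get(p, 1.0)
    cols = design_columns(predictors, age_interactions)
    X = np.empty((len(df), len(cols)))
    for j, c in enumerate(cols):
        if ":" in c:
            _, p = c.split(":", 1)
            X[:, j] = units["age"] * units[p]
        else:
            X[:, j] = units[c]
    return X, cols


def beta_vector(coeffs: CoefficientSet, columns: Iterable[str]) -> np.ndarray:
    """Coefficient vector aligned with ``design_matrix`` columns."""
    out = []
    for c in columns:
        if ":" in c:
            _, p = c.split(":", 1)
            out.append(coeffs.beta_age_interaction.get(p, 0.0))
        else:
            out.append(coeffs.beta_main.get(c, 0.0))
    return np.asarray(out)


def linear_predictor_frame(df: pd.DataFrame, coeffs: CoefficientSet) -> np.ndarray:
    """Vector of linear predictors for every row of a cohort table."""
    preds = list(coeffs.beta_main)
    X, cols = design_matrix(df, preds, age_interactions=bool(coeffs.beta_age_interaction))
    return X @ beta_vector(coeffs, cols)


def predict_risk_frame(df: pd.DataFrame, family: ModelFamily,
                       s0_overrides: Mapping[Any, Mapping[str, float]] | None = None,
                       region_col: str = "region") -> pd.DataFrame:
    """Per-row cause-specific and combined 10-year risks.

    ``s0_overrides`` optionally maps region label -> outcome -> baseline
    survival, as produced by regional recalibration; rows from regions not in
    the map fall back to the family's pooled baseline survival.
    """
    out = pd.DataFrame(index=df.index)
    for outcome, col in zip(OUTCOMES, ("risk_ihd", "risk_is", "risk_hs")):
        coeffs = family.submodels[outcome]
        lp = linear_predictor_frame(df, coeffs)
        s0 = np.full(len(df), coeffs.s0_10)
        if s0_overrides:
            regions = df[region_col].to_numpy()
            for reg, by_outcome in s0_overrides.items():
                if outcome in by_outcome:
                    s0[regions == reg] = by_outcome[outcome]
        out[col] = 1.0 - np.power(s0, np.exp(lp))
    out["risk_cvd"] = 1.0 - (1.0 - out["risk_ihd"]) * (1.0 - out["risk_is"]) * (1.0 - out["risk_hs"])
    return out
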