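"""Discrimination, calibration and incremental-value statistics.

Implements the performance measures used to report the risk models:

* Harrell's concordance index over usable pairs under right censoring, with
  ties in predicted risk counted 1/2 and an asymptotic (leave-one-subject-out
  jackknife) standard error for the 95% CI;
* the Nam–D'Agostino goodness-of-fit chi-square comparing Kaplan–Meier
  observed 10-year risk with mean predicted risk across deciles of predicted
  risk (degrees of freedom = groups - 1);
* integrated discrimination improvement (IDI) and relative IDI between a base
  and an extended model;
* a plot-ready decile calibration table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell C with jackknife standard error and 95% CI."""

    c: float
    se: float
    ci: tuple[float, float]
    n_comparable: int


def _as_arrays(risks, times, events):
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float).astype(bool)
    if not (len(r) == len(t) == len(d)):
        raise ValueError("risks, times and events must have equal length")
    return r, t, d


def harrell_c(risks, times, events, block: int = 512) -> ConcordanceResult:
    """Harrell's concordance index for right-censored data.

    A pair (i, j) is usable when subject i has an event strictly before j's
    time, or at the same recorded time as j's censoring.  The pair scores 1
    if the earlier-event subject has the higher predicted risk, 1/2 on a risk
    tie, 0 otherwise.  Two events at identical times are not comparable.

    The standard error is the leave-one-subject-out jackknife of the ratio of
    pair sums, an asymptotic SE appropriate for large samples.
    """
    r, t, d = _as_arrays(risks, times, events)
    n = len(r)
    ev = np.flatnonzero(d)
    # per-subject usable-pair and win counts (each pair credited to both ends)
    u = np.zeros(n)
    w = np.zeros(n)
    for start in range(0, len(ev), block):
        idx = ev[start:start + block]
        dt = t[None, :] - t[idx, None]
        comparable = (dt > 0) | ((dt == 0) & ~d[None, :])
        comparable[np.arange(len(idx)), idx] = False
        wins = (r[idx, None] > r[None, :]).astype(float)
        wins += 0.5 * (r[idx, None] == r[None, :])
        score = wins * comparable
        u[idx] += comparable.sum(axis=1)
        w[idx] += score.sum(axis=1)
        u += comparable.sum(axis=0)
        w += score.sum(axis=0)
    P = u.sum() / 2.0  # each pair was credited to both members
    S = w.sum() / 2.0
    if P < 1:
        raise ValueError("no comparable pairs; concordance undefined")
    c = S / P
    # jackknife over subjects: removing k removes exactly the pairs involving k
    denom = P - u
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = np.where(denom > 0, (S - w) / np.where(denom > 0, denom, 1.0), c)
    se = float(np.sqrt((n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)))
    ci = (max(0.0, c - Z95 * se), min(1.0, c + Z95 * se))
    return ConcordanceResult(c=float(c), se=se, ci=ci, n_comparable=int(round(P)))


def km_observed_risk(times, events, horizon: float,
                     with_ci: bool = False):
    """Kaplan–Meier observed risk (1 - S(horizon)), optionally with 95% CI."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    kmf = KaplanMeierFitter()
    kmf.fit(t, d)
    surv = float(kmf.predict(horizon))
    if not with_ci:
        return 1.0 - surv
    ci = kmf.confidence_interval_survival_function_
    rows = ci[ci.index <= horizon]
    if len(rows):
        lo_s, hi_s = float(rows.iloc[-1, 0]), float(rows.iloc[-1, 1])
    else:
        lo_s = hi_s = 1.0
    return 1.0 - surv, (1.0 - hi_s, 1.0 - lo_s)


def risk_groups(risks, groups: int = 10) -> np.ndarray:
    """Group labels 0..groups-1 by quantiles of predicted risk.

    Values equal to an internal boundary are assigned to the lower group.
    """
    r = np.asarray(risks, dtype=float)
    edges = np.quantile(r, np.linspace(0, 1, groups + 1)[1:-1])
    return np.searchsorted(edges, r, side="left")


def calibration_table(risks, times, events, horizon: float = 10.0,
                      groups: int = 10) -> pd.DataFrame:
    """Decile table of mean predicted vs Kaplan–Meier observed risk."""
    r, t, d = _as_arrays(risks, times, events)
    g = risk_groups(r, groups)
    rows = []
    for k in range(groups):
        m = g == k
        if not m.any():
            raise ValueError(f"risk group {k} is empty; cannot tabulate calibration")
        mean_pred = float(r[m].mean())
        if not (0.0 < mean_pred < 1.0):
            raise ValueError(f"risk group {k} has degenerate mean prediction {mean_pred}")
        obs, ci = km_observed_risk(t[m], d[m], horizon, with_ci=True)
        rows.append({
            "group": k + 1,
            "n": int(m.sum()),
            "mean_predicted": mean_pred,
            "observed": float(obs),
            "observed_ci_low": float(ci[0]),
            "observed_ci_high": float(ci[1]),
        })
    return pd.DataFrame(rows)


def nam_dagostino(risks, times, events, horizon: float = 10.0,
                  groups: int = 10) -> dict:
    """Nam–D'Agostino goodness-of-fit test across deciles of predicted risk.

    chi2 = sum_g n_g (KM_g - pbar_g)^2 / (pbar_g (1 - pbar_g)), compared with
    a chi-square on groups - 1 degrees of freedom.  This is one of several
    published variants of the statistic; the form here is pinned and
    oracle-tested.
    """
    table = calibration_table(risks, times, events, horizon, groups)
    chi2 = float(np.sum(
        table["n"] * (table["observed"] - table["mean_predicted"]) ** 2
        / (table["mean_predicted"] * (1.0 - table["mean_predicted"]))
    ))
    df = groups - 1
    return {
        "chi2": chi2,
        "df": df,
        "p_value": float(stats.chi2.sf(chi2, df)),
        "table": table,
    }


def idi(base_risks, new_risks, times, events, horizon: float = 10.0) -> dict:
    """Integrated discrimination improvement between two risk vectors.

    Event-by-horizon status is assigned directly: cases are subjects with an
    event at or before the horizon; controls are subjects still under
    observation at the horizon.  Subjects censored before the horizon are
    excluded from both means.
    """
    b = np.asarray(base_risks, dtype=float)
    nw = np.asarray(new_risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float).astype(bool)
    if len(b) != len(nw) or len(b) != len(t):
        raise ValueError("risk vectors must cover the same subjects")
    cases = d & (t <= horizon)
    controls = t >= horizon
    controls &= ~cases
    if not cases.any() or not controls.any():
        raise ValueError("need at least one case and one control by the horizon")
    slope_base = float(b[cases].mean() - b[controls].mean())
    slope_new = float(nw[cases].mean() - nw[controls].mean())
    value = slope_new - slope_base
    out = {
        "idi": value,
        "base_slope": slope_base,
        "new_slope": slope_new,
        "relative_idi_pct": (value / slope_base * 100.0) if slope_base != 0 else np.inf,
    }
    return out


def relative_idi(base_risks, new_risks, times, events,
                 horizon: float = 10.0) -> float:
    """Relative IDI in percent: IDI / discrimination slope of the base model."""
    return float(idi(base_risks, new_risks, times, events, horizon)["relative_idi_pct"])


def plot_calibration(table: pd.DataFrame, path, title: str | None = None) -> None:
    """Write a predicted-vs-observed decile calibration plot to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    x = table["mean_predicted"]
    y = table["observed"]
    yerr = np.vstack([
        y - table["observed_ci_low"],
        table["observed_ci_high"] - y,
    ])
    ax.errorbar(x, y, yerr=np.maximum(yerr, 0), fmt="o", color="k", capsize=2)
    lim = max(float(x.max()), float(y.max())) * 1.1 or 1.0
    ax.plot([0, lim], [0, lim], "--", color="gray", lw=1)
    ax.set_xlabel("Mean predicted 10-year risk")
    ax.set_ylabel("Observed 10-year risk (Kaplan–Meier)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def evaluate_risks(risks, times, events, horizon: float = 10.0,
                   groups: int = 10) -> dict:
    """Bundle discrimination and calibration statistics for one risk vector."""
    c = harrell_c(risks, times, events)
    nd = nam_dagostino(risks, times, events, horizon, groups)
    return {
        "n": int(len(np.asarray(risks))),
        "harrell_c": {"value": c.c, "se": c.se, "ci": list(c.ci)},
        "nam_dagostino": {"chi2": nd["chi2"], "df": nd["df"], "p_value": nd["p_value"]},
        "calibration": nd["table"].to_dict(orient="records"),
    }
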