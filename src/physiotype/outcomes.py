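"""Outcome comparison across physiotypes.

Survival machinery (Kaplan-Meier product-limit curves, log-rank tests,
Cox proportional-hazards regression with Efron tie handling) is
delegated to lifelines; this module owns the physiotype-specific
contracts: reference coding against Physiotype C, the reverse-KM
follow-up estimate, the SOFA-band covariate, group comparison tests,
and Bonferroni adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

REFERENCE_PHYSIOTYPE = "C"


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival curve with an at-risk/event table.

    Returns a step-function table: one row per distinct time with
    columns ``time, at_risk, events, censored, survival``; S(0) = 1 and
    the curve is non-increasing and right-continuous.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival data")
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
    surv = kmf.survival_function_["KM_estimate"].reindex(table["time"]).to_numpy()
    return pd.DataFrame(
        {
            "time": table["time"],
            "at_risk": table["at_risk"].astype(int),
            "events": table["observed"].astype(int),
            "censored": table["censored"].astype(int),
            "survival": surv,
        }
    )


def km_survival_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a km_estimate curve at time t (right-continuous)."""
    past = curve[curve["time"] <= t]
    return float(past["survival"].iloc[-1]) if len(past) else 1.0


def logrank_test(time, event, group) -> tuple[float, int, float]:
    """Log-rank test across two or more groups.

    Returns ``(chi2, df, p)``; with no events anywhere the statistic is
    0 and p = 1 by convention (warned).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    df = len(levels) - 1
    if event.sum() == 0:
        warnings.warn("no events in any group; log-rank statistic is 0",
                      stacklevel=2)
        return 0.0, df, 1.0
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), df, float(res.p_value)


def reverse_km_followup(time, event) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    The censoring indicator is inverted (being censored becomes the
    event) and the median of that curve is the potential follow-up
    duration.  The median is the first time the curve falls strictly
    below 0.5 (right-continuous convention); if it never does, the
    follow-up is open-ended and ``inf`` is returned.
    """
    event = np.asarray(event, dtype=int)
    curve = km_estimate(np.asarray(time, dtype=float), 1 - event)
    below = curve[curve["survival"] < 0.5 - 1e-9]
    if len(below) == 0:
        warnings.warn("reverse-KM curve never crosses 0.5; follow-up open-ended",
                      stacklevel=2)
        return float("inf")
    return float(below["time"].iloc[0])


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "time_days",
    event_col: str = "event",
    physiotype_col: str = "physiotype",
    covariates: tuple[str, ...] = (),
    reference: str = REFERENCE_PHYSIOTYPE,
) -> pd.DataFrame:
    """Cox proportional-hazards model with physiotype indicators.

    The physiotype enters as indicator columns against ``reference``
    (Physiotype C by default); additional adjustment covariates are
    passed through as-is.  Efron tie handling, Wald 95% CIs.  Returns a
    hazard table with one row per coefficient (plus a marker row for
    the reference level).
    """
    levels = sorted(data[physiotype_col].astype(str).unique())
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent")
    design = data[[duration_col, event_col, *covariates]].copy()
    indicator_cols = []
    for lev in levels:
        if lev == reference:
            continue
        col = f"{physiotype_col}_{lev}"
        design[col] = (data[physiotype_col].astype(str) == lev).astype(float)
        indicator_cols.append(col)

    n_events = int(design[event_col].sum())
    n_covs = len(indicator_cols) + len(covariates)
    if n_events < 10 * n_covs:
        warnings.warn(
            f"only {n_events} events for {n_covs} covariates "
            "(< 10 events per covariate)",
            stacklevel=2,
        )

    cph = CoxPHFitter()
    cph.fit(design, duration_col=duration_col, event_col=event_col)
    summ = cph.summary
    rows = [
        {
            "covariate": f"{physiotype_col}={reference}",
            "hr": 1.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "reference": True,
        }
    ]
    for cov in indicator_cols + list(covariates):
        s = summ.loc[cov]
        rows.append(
            {
                "covariate": cov,
                "hr": float(s["exp(coef)"]),
                "ci_low": float(s["exp(coef) lower 95%"]),
                "ci_high": float(s["exp(coef) upper 95%"]),
                "p": float(s["p"]),
                "reference": False,
            }
        )
    return pd.DataFrame(rows)


def sofa_band(sofa_total) -> pd.Categorical:
    """Band admission SOFA totals into 0-1, 2-4, >=5 (reference 0-1)."""
    vals = np.asarray(sofa_total, dtype=float)
    bands = np.where(vals <= 1, "0-1", np.where(vals <= 4, "2-4", ">=5"))
    return pd.Categorical(bands, categories=["0-1", "2-4", ">=5"], ordered=True)


def group_compare(values, labels, kind: str) -> tuple[float, float]:
    """Compare a variable across phenotype groups.

    ``kind`` selects the test: "categorical" (chi-square on the
    contingency table, no continuity correction), "continuous-normal"
    (one-way ANOVA F) or "continuous-rank" (Kruskal-Wallis H).
    Returns ``(statistic, p)``.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if kind == "categorical":
        table = pd.crosstab(labels, values)
        if (table.sum(axis=0) == 0).any():
            raise ValueError("empty category level")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    groups = [values[labels == lev].astype(float) for lev in levels]
    if kind == "continuous-normal":
        stat, p = stats.f_oneway(*groups)
    elif kind == "continuous-rank":
        stat, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(stat), float(p)


def bonferroni_adjust(p_values, family_size: int | None = None) -> list[float]:
    """Bonferroni family-wise adjustment: p_adj = min(1, m * p)."""
    p_values = list(p_values)
    m = family_size if family_size is not None else len(p_values)
    if m < len(p_values):
        raise ValueError("family_size must be >= number of p-values")
    out = []
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out
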