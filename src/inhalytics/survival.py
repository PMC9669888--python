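"""Time-to-discontinuation analysis of the monitoring program.

The endpoint is *program* discontinuation, not medication discontinuation:
a patient whose last recorded dose lies strictly more than the configured
gap (30 days) before the data cutoff is an observed discontinuation at the
day index of that last dose; everyone else is censored at their last
recorded dose.  A gap of exactly 30 days is censored.

Estimation is the Kaplan-Meier product-limit, group comparison the log-rank
test, and covariate modelling a Cox proportional-hazards fit with Efron's
approximation for tied event times (ties are heavy at day granularity).
All three are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .config import StudyConfig, age_band

#: default Cox reference levels (first level of each encoded covariate)
DEFAULT_REFERENCES = {
    "age_band": "<36",
    "category": "low",
    "regimen": "1BID",
    "sex": "female",
}


def derive_survival_table(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: StudyConfig,
    categories: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-patient survival records.

    Returns ``[patient_id, time_days, event, regimen, sex, age_band,
    category]`` where ``time_days`` is the day index of the last recorded
    dose (first dose = day 1) and ``event`` is True when the gap from last
    dose to ``config.cutoff_date`` strictly exceeds
    ``config.discontinuation_gap_days``.

    Raises if any event falls after the cutoff (data leak past cutoff).
    """
    cutoff = pd.Timestamp(config.cutoff_date)
    dates = events["timestamp"].dt.normalize()
    g = dates.groupby(events["patient_id"])
    first, last = g.min(), g.max()
    if (last > cutoff).any():
        bad = list(last.index[last > cutoff][:5])
        raise ValueError(f"events after cutoff {config.cutoff_date} for patients {bad}")
    time_days = (last - first).dt.days + 1
    gap = (cutoff - last).dt.days
    out = pd.DataFrame(
        {
            "patient_id": time_days.index,
            "time_days": time_days.to_numpy(),
            "event": (gap > config.discontinuation_gap_days).to_numpy(),
        }
    )
    meta = patients.drop_duplicates("patient_id")[["patient_id", "regimen", "sex", "age"]].copy()
    meta["age_band"] = meta["age"].map(lambda a: age_band(a if pd.notna(a) else None, coarse=True))
    out = out.merge(meta.drop(columns="age"), on="patient_id", how="left")
    if categories is not None:
        out = out.merge(categories[["patient_id", "category"]], on="patient_id", how="left")
    else:
        out["category"] = None
    return out


def km_estimate(records: pd.DataFrame, group_col: str | None = None) -> pd.DataFrame:
    """Kaplan-Meier product-limit curves, long format.

    Returns ``[group, time, survival, n_risk, n_event]`` with a time-0 row
    at survival 1 for each group.  Ties at a time are processed together;
    subjects censored at an event time remain in that time's risk set.
    """
    if records.empty:
        raise ValueError("km_estimate: no records")
    groups = [("all", records)] if group_col is None else list(records.groupby(group_col))
    pieces = []
    for name, g in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(g["time_days"], event_observed=g["event"].astype(bool))
        table = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        pieces.append(
            pd.DataFrame(
                {
                    "group": name,
                    "time": table.index.to_numpy(),
                    "survival": surv.reindex(table.index).to_numpy(),
                    "n_risk": table["at_risk"].to_numpy().astype(int),
                    "n_event": table["observed"].to_numpy().astype(int),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(
    records: pd.DataFrame, group_col: str, min_time: int | None = None
) -> LogRankResult:
    """K-sample log-rank test over pooled event times.

    ``min_time`` restricts the comparison to subjects with time strictly
    greater than the bound (used for the early-adherence analysis, which
    starts after the 15-day categorisation window).
    """
    sub = records.dropna(subset=[group_col])
    if min_time is not None:
        sub = sub[sub["time_days"] > min_time]
    labels = sub[group_col].unique()
    if len(labels) < 2:
        raise ValueError("logrank_test needs at least two non-empty groups")
    if (sub.groupby(group_col).size() == 0).any():
        raise ValueError("logrank_test: empty group")
    res = multivariate_logrank_test(
        sub["time_days"], sub[group_col], sub["event"].astype(bool)
    )
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
    )


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratios with Wald 95% CIs per non-reference covariate level."""

    table: pd.DataFrame  # index: term; columns: hr, ci_lower, ci_upper, p
    references: dict
    n: int
    n_events: int


def cox_fit(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = ("age_band", "category"),
    references: dict | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit by partial likelihood (Efron ties).

    Categorical covariates are dummy-encoded against the stated reference
    level (defaults: age <36, low early adherence).  Raises when there are
    no events, fewer than 3 usable subjects, or the partial likelihood does
    not converge (e.g. complete separation).
    """
    refs = dict(DEFAULT_REFERENCES, **(references or {}))
    sub = records.dropna(subset=list(covariates)).copy()
    if len(sub) < 3:
        raise ValueError("cox_fit: too few usable subjects (no usable risk sets)")
    if int(sub["event"].sum()) == 0:
        raise ValueError("cox_fit: no events observed")
    design = sub[["time_days", "event"]].copy()
    design["event"] = design["event"].astype(int)
    for cov in covariates:
        levels = list(pd.unique(sub[cov]))
        ref = refs.get(cov, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from covariate {cov!r}")
        ordered = [ref] + [l for l in levels if l != ref]
        cat = pd.Categorical(sub[cov], categories=ordered)
        dummies = pd.get_dummies(cat, prefix=cov, drop_first=True).astype(float)
        design = pd.concat([design, dummies.set_index(design.index)], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time_days", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            "cox_fit: partial likelihood failed to converge (possible separation); "
            f"lifelines reported: {err}"
        ) from err
    summary = cph.summary
    table = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_lower": summary["exp(coef) lower 95%"],
            "ci_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    return CoxResult(
        table=table,
        references={c: refs.get(c) for c in covariates},
        n=len(sub),
        n_events=int(sub["event"].sum()),
    )
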