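"""Adherence metrics and use-pattern profiles.

Three adherence definitions are computed over a stated day window:

* pooled (average medication) adherence — recorded maintenance actuations
  divided by prescribed maintenance inhalations, summed over the window;
* fully adherent days — proportion of patient-days on which every prescribed
  maintenance inhalation was recorded;
* zero adherence days — proportion of patient-days with no actuations.

Group summaries keep the pooled ratio-of-sums and the unweighted mean of
per-patient adherence as distinct, separately labelled quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig


def pooled_adherence(taken_sum: int, prescribed_sum: int, ndigits: int | None = 1) -> float:
    """Pooled adherence percentage, 100 * taken / prescribed.

    Reported to one decimal place by default (``ndigits=None`` for the raw
    value).
    """
    if prescribed_sum <= 0:
        raise ValueError("prescribed_sum must be positive")
    if not 0 <= taken_sum <= prescribed_sum:
        raise ValueError(f"taken_sum {taken_sum} outside [0, {prescribed_sum}]")
    pct = 100.0 * taken_sum / prescribed_sum
    return pct if ndigits is None else round(pct, ndigits)


def day_proportion(numerator_days: int, day_denominator: int, ndigits: int | None = 1) -> float:
    """Percentage of days, 100 * numerator / denominator, one decimal."""
    if day_denominator <= 0:
        raise ValueError("day_denominator must be positive")
    if not 0 <= numerator_days <= day_denominator:
        raise ValueError(f"numerator_days {numerator_days} outside [0, {day_denominator}]")
    pct = 100.0 * numerator_days / day_denominator
    return pct if ndigits is None else round(pct, ndigits)


@dataclass(frozen=True)
class AdherenceSummary:
    scope: str
    window: tuple[int, int]
    n_patients: int
    maintenance_taken_sum: int
    maintenance_prescribed_sum: int
    pooled_adherence_pct: float
    mean_patient_adherence_pct: float
    fully_adherent_days: int
    zero_dose_days: int
    day_denominator: int
    fully_adherent_pct: float
    zero_dose_pct: float


def _check_complete(days: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    lo, hi = window
    if not 1 <= lo <= hi:
        raise ValueError(f"bad window {window}")
    sub = days[(days["day_index"] >= lo) & (days["day_index"] <= hi)]
    expected = hi - lo + 1
    counts = sub.groupby("patient_id").size()
    short = counts[counts != expected]
    if len(short):
        raise ValueError(
            f"incomplete window {window}: patients {list(short.index[:5])} have "
            f"{list(short.values[:5])} of {expected} days"
        )
    return sub


def per_patient_adherence(days: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Per-patient pooled adherence over the window.

    Returns ``[patient_id, regimen, taken, prescribed, adherence_pct]`` with
    the percentage unrounded.
    """
    sub = _check_complete(days, window)
    n_days = window[1] - window[0] + 1
    g = sub.groupby("patient_id").agg(
        regimen=("regimen", "first"),
        m_prescribed=("m_prescribed", "first"),
        taken=("maintenance", "sum"),
    )
    g["prescribed"] = g["m_prescribed"] * n_days
    g["adherence_pct"] = 100.0 * g["taken"] / g["prescribed"]
    return g.drop(columns="m_prescribed").reset_index()


def summarize(
    days: pd.DataFrame, scope: str = "cohort", window: tuple[int, int] = (1, 90)
) -> AdherenceSummary:
    """Aggregate adherence over a complete window of day records.

    Requires every patient present to have one row per day in the window.
    For a single-regimen scope, ``maintenance_prescribed_sum`` equals
    M x day_denominator (the denominator-coupling invariant).
    """
    sub = _check_complete(days, window)
    per_patient = per_patient_adherence(days, window)
    taken = int(sub["maintenance"].sum())
    prescribed = int((sub["m_prescribed"]).sum())  # M per day, summed over patient-days
    day_denominator = len(sub)
    fully = int(sub["fully_adherent"].sum())
    zero = int(sub["zero_dose"].sum())
    return AdherenceSummary(
        scope=scope,
        window=window,
        n_patients=sub["patient_id"].nunique(),
        maintenance_taken_sum=taken,
        maintenance_prescribed_sum=prescribed,
        pooled_adherence_pct=pooled_adherence(taken, prescribed),
        mean_patient_adherence_pct=round(float(per_patient["adherence_pct"].mean()), 1),
        fully_adherent_days=fully,
        zero_dose_days=zero,
        day_denominator=day_denominator,
        fully_adherent_pct=day_proportion(fully, day_denominator),
        zero_dose_pct=day_proportion(zero, day_denominator),
    )


def summarize_by_regimen(
    days: pd.DataFrame, window: tuple[int, int] = (1, 90)
) -> dict[str, AdherenceSummary]:
    return {
        regimen: summarize(group, scope=regimen, window=window)
        for regimen, group in days.groupby("regimen")
    }


def moving_average(series, window: int) -> np.ndarray:
    """Centered moving average with symmetric edge shrinkage.

    At position i the half-width is ``min(window//2, i, n-1-i)``, so the
    output has the input's length and the window is never empty.  Used with
    window 3 or 5 for adherence trend curves.
    """
    if window not in (3, 5):
        raise ValueError("window must be 3 or 5")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("series must be a non-empty 1-d sequence")
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = x[i - k : i + k + 1].mean()
    return out


def adherence_trend(
    days: pd.DataFrame, window: tuple[int, int] = (1, 90), ma_window: int = 5
) -> pd.DataFrame:
    """Per-day cohort pooled adherence with moving-average smoothing.

    Returns ``[day_index, adherence_pct, smoothed_pct]`` per regimen (long
    format, column ``regimen``).
    """
    sub = _check_complete(days, window)
    rows = []
    for regimen, g in sub.groupby("regimen"):
        per_day = g.groupby("day_index").agg(
            taken=("maintenance", "sum"), prescribed=("m_prescribed", "sum")
        )
        pct = 100.0 * per_day["taken"] / per_day["prescribed"]
        smooth = moving_average(pct.to_numpy(), ma_window)
        rows.append(
            pd.DataFrame(
                {
                    "regimen": regimen,
                    "day_index": per_day.index,
                    "adherence_pct": pct.to_numpy(),
                    "smoothed_pct": smooth,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def weekday_profile(days: pd.DataFrame, window: tuple[int, int] = (1, 90)) -> pd.DataFrame:
    """Mean daily adherence percentage per weekday and regimen.

    Each patient-day weighs equally; a day's adherence fraction is
    maintenance taken / M (reliever excess never enters, so values lie in
    [0, 100]).  Empty weekday cells are NaN, not zero.
    """
    sub = _check_complete(days, window).copy()
    sub["weekday"] = pd.to_datetime(sub["date"]).dt.dayofweek
    sub["frac"] = 100.0 * sub["maintenance"] / sub["m_prescribed"]
    table = sub.pivot_table(index="weekday", columns="regimen", values="frac", aggfunc="mean")
    table = table.reindex(range(7))
    table.index = pd.Index(WEEKDAYS, name="weekday")
    return table


def time_of_day_histogram(
    annotated_events: pd.DataFrame,
    window: tuple[int, int] = (1, 90),
    bin_minutes: int = 30,
) -> pd.DataFrame:
    """Counts of all inhalations (maintenance + reliever) per clock bin.

    ``annotated_events`` must carry a ``day_index`` column (see
    :func:`inhalytics.attribution.assign_day_index`).  Bin counts sum to the
    number of events inside the day window.
    """
    if 1440 % bin_minutes:
        raise ValueError("bin_minutes must divide 1440")
    lo, hi = window
    sub = annotated_events[
        (annotated_events["day_index"] >= lo) & (annotated_events["day_index"] <= hi)
    ]
    minute = sub["timestamp"].dt.hour * 60 + sub["timestamp"].dt.minute
    bins = (minute // bin_minutes).astype(int)
    n_bins = 1440 // bin_minutes
    counts = bins.value_counts().reindex(range(n_bins), fill_value=0).sort_index()
    starts = [f"{(b * bin_minutes) // 60:02d}:{(b * bin_minutes) % 60:02d}" for b in counts.index]
    return pd.DataFrame(
        {"bin_start": starts, "minute_start": counts.index * bin_minutes, "count": counts.to_numpy()}
    )


@dataclass(frozen=True)
class HighUseReport:
    """High-use days (strictly more actuations than the threshold)."""

    threshold: int
    by_regimen: pd.DataFrame  # n_patients, n_patients_high_use, n_high_use_days, person_days
    per_patient_days: pd.Series  # high-use day counts, affected patients only
    n_patients_high_use: int
    n_high_use_days: int
    person_days: int
    rate_per_100_person_days: float
    mean_days_per_affected: float = field(default=float("nan"))
    median_days_per_affected: float = field(default=float("nan"))
    range_days_per_affected: tuple[int, int] | None = None


def detect_high_use(days: pd.DataFrame, threshold: int = 12) -> HighUseReport:
    """Tally high-use days over the supplied day records.

    The person-days denominator is simply the number of rows supplied, so
    the caller chooses the observation basis (typically full follow-up, day
    1 to each patient's last dose).  A day with exactly ``threshold``
    actuations is *not* high-use (strict inequality).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    flag = days["total"] > threshold
    per_patient = days.loc[flag].groupby("patient_id").size()
    by_regimen = (
        days.assign(high=flag)
        .groupby("regimen")
        .agg(
            n_patients=("patient_id", "nunique"),
            person_days=("patient_id", "size"),
            n_high_use_days=("high", "sum"),
        )
    )
    affected = days.loc[flag].groupby("regimen")["patient_id"].nunique()
    by_regimen["n_patients_high_use"] = affected.reindex(by_regimen.index, fill_value=0)
    n_days = int(flag.sum())
    n_pat = int(len(per_patient))
    person_days = int(len(days))
    rate = round(100.0 * n_days / person_days, 2) if person_days else float("nan")
    return HighUseReport(
        threshold=threshold,
        by_regimen=by_regimen.reset_index(),
        per_patient_days=per_patient,
        n_patients_high_use=n_pat,
        n_high_use_days=n_days,
        person_days=person_days,
        rate_per_100_person_days=rate,
        mean_days_per_affected=n_days / n_pat if n_pat else float("nan"),
        median_days_per_affected=float(per_patient.median()) if n_pat else float("nan"),
        range_days_per_affected=(int(per_patient.min()), int(per_patient.max())) if n_pat else None,
    )


CATEGORY_LABELS = ("low", "medium", "high")


def categorize_early_adherence(days: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Label patients low/medium/high by pooled adherence over days 1..N.

    N is ``config.category_window_days`` (15 by default); with the default
    cutoffs, low is [0, 70), medium [70, 90) and high [90, 100].  Patients
    whose follow-up (last recorded dose day) is shorter than N are returned
    with a null label (excluded from category-stratified analyses).
    """
    n = config.category_window_days
    lo_cut, hi_cut = config.category_cutoffs
    follow_up = days.groupby("patient_id")["day_index"].max()
    rows = []
    for pid, g in days.groupby("patient_id"):
        if follow_up[pid] < n:
            rows.append((pid, float("nan"), None))
            continue
        early = g[g["day_index"] <= n]
        taken = int(early["maintenance"].sum())
        prescribed = int(early["m_prescribed"].sum())
        basis = 100.0 * taken / prescribed
        if basis < lo_cut:
            label = "low"
        elif basis < hi_cut:
            label = "medium"
        else:
            label = "high"
        rows.append((pid, basis, label))
    return pd.DataFrame(rows, columns=["patient_id", "basis_pct", "category"])
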