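"""Patient-day bucketing and maintenance/reliever dose attribution.

The monitoring device records actuations, not intent, so maintenance and
reliever use cannot be distinguished directly.  The analysis convention is
count-ordered: on each calendar day (midnight to 23:59, local wall-clock
date taken at face value) the first M recorded actuations count as the
prescribed maintenance inhalations (M = 2 for 1-BID regimens, 4 for 2-BID);
every actuation beyond M counts as reliever use.  The rule applies uniformly
to maintenance-only and MART regimens.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import attach_maintenance

DAILY_COLUMNS = [
    "patient_id",
    "day_index",
    "date",
    "total",
    "maintenance",
    "reliever",
    "fully_adherent",
    "zero_dose",
    "high_use",
]


def assign_day_index(events: pd.DataFrame) -> pd.DataFrame:
    """Annotate one patient's events with 1-based day indices.

    Day 1 is the calendar date of the first recorded inhalation; an event at
    23:59 and the next at 00:00 land on consecutive day indices.  Gap days
    produce no annotation here (they are materialised by
    :func:`materialize_days`).
    """
    if events.empty:
        raise ValueError("assign_day_index: patient has no events")
    if events["patient_id"].nunique() > 1:
        raise ValueError("assign_day_index expects events of a single patient")
    out = events.copy()
    dates = out["timestamp"].dt.normalize()
    out["day_index"] = (dates - dates.min()).dt.days + 1
    return out


def materialize_days(
    annotated: pd.DataFrame,
    m_prescribed: int,
    window_end_day: int | None = None,
    high_use_threshold: int = 12,
) -> pd.DataFrame:
    """Build one row per day index 1..window_end_day for one patient.

    Days with no actuations inside the window become explicit zero-dose
    rows.  ``window_end_day`` defaults to the day of the last event; a
    window extending past it yields trailing zero-dose days (the caller
    controls the window).  Flags follow the attribution rule:
    ``maintenance = min(total, M)``, ``reliever = total - maintenance``,
    ``fully_adherent ⇔ maintenance == M``, ``zero_dose ⇔ total == 0`` and
    ``high_use ⇔ total > high_use_threshold`` (strict).
    """
    if m_prescribed <= 0:
        raise ValueError("m_prescribed must be positive")
    last_day = int(annotated["day_index"].max())
    if window_end_day is None:
        window_end_day = last_day
    if window_end_day < 1:
        raise ValueError("window_end_day must be >= 1")
    patient_id = annotated["patient_id"].iloc[0]
    first_date = annotated["timestamp"].dt.normalize().min()

    in_window = annotated[annotated["day_index"] <= window_end_day]
    counts = in_window.groupby("day_index").size()
    idx = pd.RangeIndex(1, window_end_day + 1, name="day_index")
    total = counts.reindex(idx, fill_value=0).to_numpy()

    maintenance = np.minimum(total, m_prescribed)
    reliever = total - maintenance
    days = pd.DataFrame(
        {
            "patient_id": patient_id,
            "day_index": idx,
            "date": (first_date + pd.to_timedelta(idx - 1, unit="D")).date,
            "total": total,
            "maintenance": maintenance,
            "reliever": reliever,
            "fully_adherent": maintenance == m_prescribed,
            "zero_dose": total == 0,
            "high_use": total > high_use_threshold,
        }
    )
    return days.reset_index(drop=True)


def split_maintenance_reliever(day_records: pd.DataFrame) -> tuple[int, int]:
    """Total (maintenance, reliever) over a set of day records.

    The records must belong to one patient on one regimen; conservation
    ``maintenance + reliever == total`` holds by construction.
    """
    if day_records["patient_id"].nunique() > 1:
        raise ValueError("split_maintenance_reliever expects a single patient")
    if "regimen" in day_records.columns and day_records["regimen"].nunique() > 1:
        raise ValueError("mixed regimens in day records")
    return int(day_records["maintenance"].sum()), int(day_records["reliever"].sum())


def daily_table(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: StudyConfig,
    window_end_day: int | None = None,
) -> pd.DataFrame:
    """Per-patient-day table for every patient in ``patients``.

    When ``window_end_day`` is None each patient's window runs to their own
    last recorded dose (full follow-up; this is the person-days basis for
    high-use rates).  A fixed window yields exactly ``window_end_day`` rows
    per patient, including trailing zero-dose days.

    Adds ``regimen`` and ``m_prescribed`` columns for downstream grouping.
    """
    patients = attach_maintenance(patients)
    pieces = []
    for row in patients.itertuples(index=False):
        stream = events[events["patient_id"] == row.patient_id]
        if stream.empty:
            raise ValueError(f"daily_table: patient {row.patient_id} has no events")
        annotated = assign_day_index(stream)
        days = materialize_days(
            annotated,
            m_prescribed=row.m_prescribed,
            window_end_day=window_end_day,
            high_use_threshold=config.high_use_threshold,
        )
        days["regimen"] = row.regimen
        days["m_prescribed"] = row.m_prescribed
        pieces.append(days)
    if not pieces:
        return pd.DataFrame(columns=DAILY_COLUMNS + ["regimen", "m_prescribed"])
    return pd.concat(pieces, ignore_index=True)


def write_daily_table(days: pd.DataFrame, path) -> None:
    days.to_csv(path, index=False)
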