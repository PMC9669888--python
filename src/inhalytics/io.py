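"""Reading and validating event logs and the patient registry.

File formats
------------
Event log: delimited text with header ``patient_id,timestamp``; one row per
inhaler actuation, ISO 8601 local timestamps without a zone suffix (the
device reports local wall-clock time).

Registry: delimited text with header ``patient_id,regimen,sex,age``; one row
per patient per regimen.  Sex and age may be blank (kept as missing markers;
patients with missing demographics are only dropped from the stratified
demographic tables, never from the adherence analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import REGIMEN_CODES, SEX_LEVELS, StudyConfig, maintenance_per_day

EXCLUDE_NO_EVENTS = "no_events"
EXCLUDE_MULTIPLE_REGIMENS = "multiple_regimens"
EXCLUDE_SHORT_ENROLLMENT = "lt_min_enrollment"


class EventLogError(ValueError):
    """Malformed event log (bad header or unparseable timestamps)."""


class RegistryError(ValueError):
    """Malformed patient registry."""


def parse_event_log(path: str | Path) -> pd.DataFrame:
    """Read an actuation log into a DataFrame ``[patient_id, timestamp]``.

    Rows are returned in file order; identical timestamps for one patient are
    all retained (the device may record several actuations within a minute).

    Raises
    ------
    EventLogError
        If the header is wrong or any timestamp fails to parse; the message
        names the offending line numbers (1-based, header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, skip_blank_lines=False)
    required = ["patient_id", "timestamp"]
    if list(df.columns[:2]) != required:
        raise EventLogError(
            f"{path}: expected header columns {required}, found {list(df.columns)}"
        )
    if df.empty:
        warnings.warn(f"{path}: event log is empty", stacklevel=2)
        return pd.DataFrame({"patient_id": pd.Series(dtype=str),
                             "timestamp": pd.Series(dtype="datetime64[ns]")})
    if df["patient_id"].isna().any() or (df["patient_id"].str.strip() == "").any():
        bad = df.index[df["patient_id"].isna() | (df["patient_id"].str.strip() == "")]
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise EventLogError(f"{path}: empty patient_id at line(s) {lines}")
    parsed = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = df.index[parsed.isna()]
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise EventLogError(f"{path}: unparseable timestamp at line(s) {lines}")
    out = pd.DataFrame({"patient_id": df["patient_id"], "timestamp": parsed})
    return out


def parse_patient_table(path: str | Path) -> pd.DataFrame:
    """Read the registry into ``[patient_id, regimen, sex, age]``.

    A patient may legitimately appear on several rows with *different*
    regimens (a regimen change during the study); such patients are flagged
    and excluded downstream by :func:`apply_inclusion`.  An exact duplicate
    (same patient, same regimen) is a data error.

    Sex is normalised to ``female``/``male``/``missing``; age is a nullable
    integer (missing allowed).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "regimen": str, "sex": str})
    required = ["patient_id", "regimen", "sex", "age"]
    if list(df.columns[:4]) != required:
        raise RegistryError(
            f"{path}: expected header columns {required}, found {list(df.columns)}"
        )
    if df["patient_id"].isna().any():
        raise RegistryError(f"{path}: empty patient_id")
    bad_regimen = ~df["regimen"].isin(REGIMEN_CODES)
    if bad_regimen.any():
        codes = sorted(df.loc[bad_regimen, "regimen"].astype(str).unique())
        raise RegistryError(
            f"{path}: unknown regimen code(s) {codes}; expected {list(REGIMEN_CODES)}"
        )
    dupes = df.duplicated(subset=["patient_id", "regimen"], keep=False)
    if dupes.any():
        ids = sorted(df.loc[dupes, "patient_id"].unique())
        raise RegistryError(f"{path}: duplicate patient_id rows for {ids}")

    sex = (
        df["sex"].fillna("missing").str.strip().str.lower().replace({"": "missing", "f": "female", "m": "male"})
    )
    if not sex.isin(SEX_LEVELS).all():
        bad = sorted(sex[~sex.isin(SEX_LEVELS)].unique())
        raise RegistryError(f"{path}: unrecognised sex value(s) {bad}")
    age = pd.to_numeric(df["age"], errors="raise").astype("Int64")
    if (age.dropna() < 0).any():
        raise RegistryError(f"{path}: negative age")
    return pd.DataFrame(
        {"patient_id": df["patient_id"], "regimen": df["regimen"], "sex": sex, "age": age}
    )


@dataclass(frozen=True)
class InclusionResult:
    """Outcome of the analysis-population filter.

    Attributes
    ----------
    patients
        Registry rows of included patients (one row each), with an added
        ``last_day`` column, the day index of the last recorded actuation
        (day of first inhalation = day 1).
    events
        Event rows restricted to included patients (file order preserved).
    exclusions
        ``[patient_id, reason]`` with reason in ``{no_events,
        multiple_regimens, lt_min_enrollment}``.
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    exclusions: pd.DataFrame


def last_dose_day_index(events: pd.DataFrame) -> pd.Series:
    """Per-patient day index of the last actuation (first-dose day = 1)."""
    dates = events["timestamp"].dt.normalize()
    grouped = dates.groupby(events["patient_id"])
    return ((grouped.max() - grouped.min()).dt.days + 1).rename("last_day")


def apply_inclusion(
    events: pd.DataFrame, patients: pd.DataFrame, config: StudyConfig
) -> InclusionResult:
    """Apply the analysis-population rules.

    A patient is included iff they hold exactly one regimen, have at least
    one recorded actuation, and the day index of their last actuation is at
    least ``config.min_enrollment_days`` (so a last dose on day 90 with the
    default config is included).  Exclusion is a result, not an error.
    """
    registry_ids = patients["patient_id"]
    multi = patients.groupby("patient_id")["regimen"].nunique()
    multi_ids = set(multi.index[multi > 1])

    last_day = last_dose_day_index(events)
    have_events = set(last_day.index)

    exclusions = []
    for pid in registry_ids.unique():
        if pid in multi_ids:
            exclusions.append((pid, EXCLUDE_MULTIPLE_REGIMENS))
        elif pid not in have_events:
            exclusions.append((pid, EXCLUDE_NO_EVENTS))
        elif last_day[pid] < config.min_enrollment_days:
            exclusions.append((pid, EXCLUDE_SHORT_ENROLLMENT))
    excluded_ids = {pid for pid, _ in exclusions}

    keep = patients[~patients["patient_id"].isin(excluded_ids)].drop_duplicates("patient_id")
    keep = keep.merge(last_day, left_on="patient_id", right_index=True, how="left")
    kept_events = events[events["patient_id"].isin(set(keep["patient_id"]))].reset_index(drop=True)
    excl = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return InclusionResult(patients=keep.reset_index(drop=True), events=kept_events, exclusions=excl)


def attach_maintenance(patients: pd.DataFrame) -> pd.DataFrame:
    """Add the prescribed maintenance inhalations/day column ``m_prescribed``."""
    out = patients.copy()
    out["m_prescribed"] = out["regimen"].map(maintenance_per_day)
    return out
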