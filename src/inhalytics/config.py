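"""Study configuration, regimen vocabulary and age-band definitions.

The analysis concerns budesonide/formoterol Turbuhaler users monitored by a
clip-on electronic device.  Patients are prescribed one of four regimens:

* ``1BID``   — 1 inhalation twice daily (2 maintenance inhalations/day)
* ``1BID_R`` — 1-BID plus as-needed reliever from the same inhaler (MART)
* ``2BID``   — 2 inhalations twice daily (4 maintenance inhalations/day)
* ``2BID_R`` — 2-BID plus as-needed reliever (MART)

The ``_R`` suffix marks maintenance-and-reliever therapy; the prescribed
maintenance load is identical with or without the reliever component.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import yaml

#: regimen code -> prescribed maintenance inhalations per day (M)
REGIMEN_MAINTENANCE: dict[str, int] = {
    "1BID": 2,
    "1BID_R": 2,
    "2BID": 4,
    "2BID_R": 4,
}

REGIMEN_CODES: tuple[str, ...] = tuple(REGIMEN_MAINTENANCE)

SEX_LEVELS: tuple[str, ...] = ("female", "male", "missing")


def is_reliever_regimen(regimen: str) -> bool:
    """True for maintenance-and-reliever (MART) regimens (``*_R`` codes)."""
    return regimen.endswith("_R")


def maintenance_per_day(regimen: str) -> int:
    try:
        return REGIMEN_MAINTENANCE[regimen]
    except KeyError:
        raise ValueError(
            f"unknown regimen code {regimen!r}; expected one of {REGIMEN_CODES}"
        ) from None


# Reporting age bands.  Fine bands drive the demographics table; coarse bands
# (<36, 36-55, >55) are the covariate encoding for the discontinuation model,
# with <36 as the reference level.
FINE_AGE_BANDS: tuple[tuple[str, int | None, int | None], ...] = (
    ("<18", None, 17),
    ("18-25", 18, 25),
    ("26-35", 26, 35),
    ("36-45", 36, 45),
    ("46-55", 46, 55),
    ("56-65", 56, 65),
    ("66-75", 66, 75),
    (">75", 76, None),
)

COARSE_AGE_BANDS: tuple[tuple[str, int | None, int | None], ...] = (
    ("<36", None, 35),
    ("36-55", 36, 55),
    (">55", 56, None),
)

FINE_AGE_BAND_LABELS = tuple(label for label, _, _ in FINE_AGE_BANDS)
COARSE_AGE_BAND_LABELS = tuple(label for label, _, _ in COARSE_AGE_BANDS)


def age_band(age_years, coarse: bool = False) -> str | None:
    """Map an age in years onto a reporting band; ``None`` if age is missing."""
    if age_years is None:
        return None
    try:
        age = int(age_years)
    except (TypeError, ValueError):
        return None
    if age < 0:
        raise ValueError(f"negative age: {age_years!r}")
    bands = COARSE_AGE_BANDS if coarse else FINE_AGE_BANDS
    for label, lo, hi in bands:
        if (lo is None or age >= lo) and (hi is None or age <= hi):
            return label
    raise AssertionError("age bands must partition the age axis")


@dataclass(frozen=True)
class StudyConfig:
    """Analysis parameters.

    Parameters
    ----------
    cutoff_date
        Administrative data cutoff; a patient whose last recorded dose lies
        more than ``discontinuation_gap_days`` before this date counts as
        having discontinued the monitoring program.
    min_enrollment_days
        Minimum day index of the last recorded actuation (day of first
        inhalation = day 1) for inclusion in the analysis set.
    discontinuation_gap_days
        Gap to cutoff, in days, beyond which (strictly) a patient is an
        observed discontinuation rather than censored.
    high_use_threshold
        A day with strictly more actuations than this counts as a high-use
        day (default 12, i.e. >12 actuations).
    category_window_days
        Early-adherence categorisation window (days 1..N inclusive).
    category_cutoffs
        Percent cutoffs (low/medium and medium/high); low < c0 <= medium <
        c1 <= high.
    ma_window
        Moving-average window for trend smoothing, 3 or 5 days.
    adherence_window_days
        Window over which per-patient and group adherence summaries are
        computed (days 1..N inclusive).
    """

    cutoff_date: dt.date
    min_enrollment_days: int = 90
    discontinuation_gap_days: int = 30
    high_use_threshold: int = 12
    category_window_days: int = 15
    category_cutoffs: tuple[float, float] = (70.0, 90.0)
    ma_window: int = 5
    adherence_window_days: int = 90

    def __post_init__(self) -> None:
        if not isinstance(self.cutoff_date, dt.date):
            raise TypeError("cutoff_date must be a datetime.date")
        for name in (
            "min_enrollment_days",
            "discontinuation_gap_days",
            "high_use_threshold",
            "category_window_days",
            "adherence_window_days",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        lo, hi = self.category_cutoffs
        if not (0.0 < lo < hi <= 100.0):
            raise ValueError(
                f"category_cutoffs must be strictly increasing in (0, 100], got {self.category_cutoffs}"
            )
        if self.ma_window not in (3, 5):
            raise ValueError(f"ma_window must be 3 or 5, got {self.ma_window!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cutoff_date" not in raw:
            raise ValueError(f"{path}: config must set cutoff_date")
        cutoff = raw["cutoff_date"]
        if isinstance(cutoff, str):
            cutoff = dt.date.fromisoformat(cutoff)
        kwargs = {k: v for k, v in raw.items() if k != "cutoff_date"}
        if "category_cutoffs" in kwargs:
            kwargs["category_cutoffs"] = tuple(float(c) for c in kwargs["category_cutoffs"])
        return cls(cutoff_date=cutoff, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "cutoff_date": self.cutoff_date.isoformat(),
            "min_enrollment_days": self.min_enrollment_days,
            "discontinuation_gap_days": self.discontinuation_gap_days,
            "high_use_threshold": self.high_use_threshold,
            "category_window_days": self.category_window_days,
            "category_cutoffs": list(self.category_cutoffs),
            "ma_window": self.ma_window,
            "adherence_window_days": self.adherence_window_days,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
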