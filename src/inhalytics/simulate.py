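"""Seeded behavioural cohort simulator.

Generates event logs and registries with the structure the analysis
pipeline assumes, plus a truth file recording every latent quantity so that
parameter-recovery tests can compare pipeline estimates against the
generating process.

The generative model, per patient:

* a regimen drawn from the cohort mix, fixing M (2 or 4 maintenance
  inhalations/day) and the reliever flag;
* an adherence propensity p ~ Beta(a, b) (default mean 0.70, SD ~0.24,
  matching the between-patient spread seen in electronically monitored
  cohorts);
* each day, each of the M scheduled inhalations is taken independently with
  probability p, multiplied by a weekend factor on Fridays/Saturdays/
  Sundays (routine disruption); taken morning slots get clock times from a
  Gaussian around 08:00, evening slots around 20:00 (bimodal dosing);
* MART (``*_R``) regimens add Poisson-distributed extra reliever doses at
  uniform times;
* rarely, a day is inflated to 13-20 actuations (device experimentation /
  symptom flares), producing high-use days;
* dropout follows a discrete-time daily hazard with multipliers for age
  under 36 and low adherence propensity, and a hazard bump around days
  30-40 (the first canister running out); after the dropout day no events
  are generated, which is what makes the 30-day discontinuation rule fire.

All randomness flows from one seeded ``numpy.random.Generator``; a fixed
seed reproduces the output files byte for byte.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import REGIMEN_CODES, StudyConfig, is_reliever_regimen, maintenance_per_day

# Age sampling ranges per fine band (label, lo, hi inclusive)
_AGE_RANGES = (
    (12, 17), (18, 25), (26, 35), (36, 45), (46, 55), (56, 65), (66, 75), (76, 85),
)


@dataclass(frozen=True)
class DropoutParams:
    """Discrete-time daily dropout hazard and its multipliers."""

    base_hazard: float = 0.005
    age_lt36_multiplier: float = 1.5
    low_adherence_multiplier: float = 1.8
    low_adherence_cutoff: float = 0.7  # propensity below this is "low"
    bump_multiplier: float = 2.5
    bump_days: tuple[int, int] = (30, 40)


@dataclass(frozen=True)
class SimulationParams:
    """Full generative specification of a synthetic cohort."""

    n_patients: int = 661
    # 1BID, 1BID_R, 2BID, 2BID_R cohort shares
    regimen_mix: tuple[float, ...] = (0.085, 0.546, 0.067, 0.302)
    sex_mix: tuple[float, ...] = (0.538, 0.457, 0.005)  # female, male, missing
    age_band_mix: tuple[float, ...] = (
        0.0669, 0.1383, 0.1687, 0.1778, 0.2508, 0.1307, 0.0547, 0.0121,
    )
    adherence_beta: tuple[float, float] = (1.85, 0.79)  # mean 0.70, SD ~0.24
    weekend_factor: float = 0.90  # take-probability multiplier Fri/Sat/Sun
    morning_time: tuple[float, float] = (480.0, 60.0)  # minutes: mean, sd
    evening_time: tuple[float, float] = (1200.0, 60.0)
    reliever_rate: float = 0.3  # Poisson extra doses/day, _R regimens only
    high_use_day_prob: float = 3e-4  # per-day chance of a 13-20 actuation day
    dropout: DropoutParams = field(default_factory=DropoutParams)
    horizon_days: int = 180
    start_date: dt.date = dt.date(2018, 1, 1)
    per_day_mode: bool = False  # all-or-nothing daily dosing instead of per-slot
    id_prefix: str = "P"  # patient-id prefix (distinct prefixes allow merging cohorts)
    seed: int = 0

    @property
    def cutoff_date(self) -> dt.date:
        """Administrative cutoff: the last day of the simulation horizon."""
        return self.start_date + dt.timedelta(days=self.horizon_days - 1)

    def validate(self) -> None:
        for name in ("regimen_mix", "sex_mix", "age_band_mix"):
            mix = getattr(self, name)
            if any(w < 0 for w in mix) or not np.isclose(sum(mix), 1.0, atol=1e-6):
                raise ValueError(f"{name} must be non-negative and sum to 1, got {mix}")
        if len(self.regimen_mix) != 4 or len(self.sex_mix) != 3 or len(self.age_band_mix) != 8:
            raise ValueError("mix vectors have wrong length")
        a, b = self.adherence_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta shapes must be positive")
        for name in ("weekend_factor", "reliever_rate", "high_use_day_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")

    def study_config(self, **overrides) -> StudyConfig:
        """Matching analysis configuration (cutoff at the horizon end)."""
        return StudyConfig(cutoff_date=self.cutoff_date, **overrides)


def sample_dropout(
    propensity: float, age_years: int, params: SimulationParams, rng: np.random.Generator
) -> int | None:
    """Draw a dropout day (last active day) or None for the full horizon.

    The daily hazard is base x age multiplier (age < 36) x low-adherence
    multiplier (propensity below the cutoff) x bump multiplier inside the
    bump-day interval, clipped to 1.
    """
    d = params.dropout
    lo, hi = d.bump_days
    for day in range(1, params.horizon_days + 1):
        h = d.base_hazard
        if age_years < 36:
            h *= d.age_lt36_multiplier
        if propensity < d.low_adherence_cutoff:
            h *= d.low_adherence_multiplier
        if lo <= day <= hi:
            h *= d.bump_multiplier
        if rng.random() < min(h, 1.0):
            return day
    return None


def simulate_patient_day(
    propensity: float,
    weekday: int,
    regimen: str,
    params: SimulationParams,
    rng: np.random.Generator,
) -> list[int]:
    """Simulate one active day; returns sorted actuation times in minutes.

    The M scheduled slots split first-half-morning / second-half-evening
    (M=2 gives one of each, M=4 two of each).  ``weekday`` is Monday=0; the
    weekend factor applies on Friday (4), Saturday (5) and Sunday (6).
    """
    m = maintenance_per_day(regimen)
    p = propensity * (params.weekend_factor if weekday >= 4 else 1.0)
    p = min(p, 1.0)
    n_morning = m // 2
    minutes: list[int] = []

    if params.per_day_mode:
        taken = list(range(m)) if rng.random() < p else []
    else:
        taken = [slot for slot in range(m) if rng.random() < p]
    for slot in taken:
        mean, sd = params.morning_time if slot < n_morning else params.evening_time
        t = rng.normal(mean, sd)
        minutes.append(int(min(max(t, 0.0), 1439.0)))  # clip to the day, no wrap

    if is_reliever_regimen(regimen) and params.reliever_rate > 0:
        extra = rng.poisson(params.reliever_rate)
        minutes.extend(int(t) for t in rng.integers(0, 1440, size=extra))

    if params.high_use_day_prob > 0 and rng.random() < params.high_use_day_prob:
        target = int(rng.integers(13, 21))
        while len(minutes) < target:
            minutes.append(int(rng.integers(0, 1440)))

    return sorted(minutes)


@dataclass(frozen=True)
class SimulatedCohort:
    events: pd.DataFrame  # patient_id, timestamp
    registry: pd.DataFrame  # patient_id, regimen, sex, age
    truth: dict  # parameters echo + per-patient latents


def simulate_cohort(params: SimulationParams, seed: int | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort (reproducible given the seed)."""
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_patients

    regimens = rng.choice(REGIMEN_CODES, size=n, p=params.regimen_mix)
    sexes = rng.choice(["female", "male", "missing"], size=n, p=params.sex_mix)
    bands = rng.choice(len(_AGE_RANGES), size=n, p=params.age_band_mix)
    ages = np.array(
        [rng.integers(_AGE_RANGES[b][0], _AGE_RANGES[b][1] + 1) for b in bands]
    )
    props = rng.beta(*params.adherence_beta, size=n)

    event_rows: list[tuple[str, str]] = []
    truth_patients = []
    for i in range(n):
        pid = f"{params.id_prefix}{i + 1:04d}"
        p, regimen, age = float(props[i]), str(regimens[i]), int(ages[i])
        dropout_day = sample_dropout(p, age, params, rng)
        last_active = params.horizon_days if dropout_day is None else min(dropout_day, params.horizon_days)
        intended = 0
        for day in range(1, last_active + 1):
            date = params.start_date + dt.timedelta(days=day - 1)
            minutes = simulate_patient_day(p, date.weekday(), regimen, params, rng)
            intended += maintenance_per_day(regimen)
            for t in minutes:
                stamp = f"{date.isoformat()}T{t // 60:02d}:{t % 60:02d}"
                event_rows.append((pid, stamp))
        truth_patients.append(
            {
                "patient_id": pid,
                "propensity": p,
                "dropout_day": dropout_day,
                "regimen": regimen,
                "sex": str(sexes[i]),
                "age": age,
                "low_adherence": bool(p < params.dropout.low_adherence_cutoff),
                "intended_maintenance": intended,
            }
        )

    events = pd.DataFrame(event_rows, columns=["patient_id", "timestamp"])
    events["timestamp"] = pd.to_datetime(events["timestamp"], format="ISO8601")
    registry = pd.DataFrame(
        {
            "patient_id": [t["patient_id"] for t in truth_patients],
            "regimen": [t["regimen"] for t in truth_patients],
            "sex": [t["sex"] if t["sex"] != "missing" else "" for t in truth_patients],
            "age": ages,
        }
    )
    truth = {
        "params": _params_dict(params),
        "patients": truth_patients,
    }
    return SimulatedCohort(events=events, registry=registry, truth=truth)


def _params_dict(params: SimulationParams) -> dict:
    d = asdict(params)
    d["start_date"] = params.start_date.isoformat()
    d["cutoff_date"] = params.cutoff_date.isoformat()
    return d


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write events.csv, registry.csv and truth.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "registry": out / "registry.csv",
        "truth": out / "truth.json",
    }
    ev = cohort.events.copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    ev.to_csv(paths["events"], index=False)
    cohort.registry.to_csv(paths["registry"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return paths


def load_params(path: str | Path) -> SimulationParams:
    """Read simulation parameters from a YAML mapping of field names."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "start_date" in raw and isinstance(raw["start_date"], str):
        raw["start_date"] = dt.date.fromisoformat(raw["start_date"])
    if "dropout" in raw and isinstance(raw["dropout"], dict):
        drop = dict(raw["dropout"])
        if "bump_days" in drop:
            drop["bump_days"] = tuple(drop["bump_days"])
        raw["dropout"] = DropoutParams(**drop)
    for key in ("regimen_mix", "sex_mix", "age_band_mix", "adherence_beta",
                "morning_time", "evening_time"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationParams(**raw)
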