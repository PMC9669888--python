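"""End-to-end analysis orchestration: raw files -> all output tables."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import attribution, cohort_stats, metrics, survival
from .config import StudyConfig
from .io import InclusionResult, apply_inclusion, parse_event_log, parse_patient_table


@dataclass
class AnalysisResult:
    inclusion: InclusionResult
    days_full: pd.DataFrame        # day 1 .. each patient's last dose (person-days basis)
    days_window: pd.DataFrame      # day 1 .. adherence window, all patients
    cohort_summary: metrics.AdherenceSummary
    regimen_summaries: dict[str, metrics.AdherenceSummary]
    per_patient: pd.DataFrame
    weekday: pd.DataFrame
    histogram: pd.DataFrame
    high_use: metrics.HighUseReport
    categories: pd.DataFrame
    survival_table: pd.DataFrame
    km_by_category: pd.DataFrame
    logrank_by_category: survival.LogRankResult | None
    report_tables: dict[str, pd.DataFrame]


def run_analysis(
    events: pd.DataFrame, patients: pd.DataFrame, config: StudyConfig
) -> AnalysisResult:
    """Run the full pipeline on parsed inputs."""
    inc = apply_inclusion(events, patients, config)
    if inc.patients.empty:
        raise ValueError("no patients satisfy the inclusion rules")

    days_full = attribution.daily_table(inc.events, inc.patients, config)
    window = (1, config.adherence_window_days)
    # Trailing zero-dose days inside the fixed window are materialised per patient.
    days_window = attribution.daily_table(
        inc.events, inc.patients, config, window_end_day=config.adherence_window_days
    )

    cohort_summary = metrics.summarize(days_window, scope="cohort", window=window)
    regimen_summaries = metrics.summarize_by_regimen(days_window, window=window)
    per_patient = metrics.per_patient_adherence(days_window, window=window)
    weekday = metrics.weekday_profile(days_window, window=window)

    annotated = []
    for pid, stream in inc.events.groupby("patient_id"):
        annotated.append(attribution.assign_day_index(stream))
    annotated_events = pd.concat(annotated, ignore_index=True)
    histogram = metrics.time_of_day_histogram(annotated_events, window=window)

    high_use = metrics.detect_high_use(days_full, threshold=config.high_use_threshold)
    categories = metrics.categorize_early_adherence(days_full, config)

    surv = survival.derive_survival_table(inc.events, inc.patients, config, categories=categories)
    with_cat = surv.dropna(subset=["category"])
    km_by_category = survival.km_estimate(with_cat, group_col="category")
    logrank = None
    if with_cat["category"].nunique() >= 2:
        logrank = survival.logrank_test(
            with_cat, "category", min_time=config.category_window_days
        )

    report_tables = cohort_stats.build_report(inc.patients, per_patient, high_use)
    return AnalysisResult(
        inclusion=inc,
        days_full=days_full,
        days_window=days_window,
        cohort_summary=cohort_summary,
        regimen_summaries=regimen_summaries,
        per_patient=per_patient,
        weekday=weekday,
        histogram=histogram,
        high_use=high_use,
        categories=categories,
        survival_table=surv,
        km_by_category=km_by_category,
        logrank_by_category=logrank,
        report_tables=report_tables,
    )


def run_analysis_files(
    events_path, patients_path, config: StudyConfig | str | Path
) -> AnalysisResult:
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    events = parse_event_log(events_path)
    patients = parse_patient_table(patients_path)
    return run_analysis(events, patients, config)


def _summary_row(s: metrics.AdherenceSummary) -> dict:
    return {
        "scope": s.scope,
        "n_patients": s.n_patients,
        "maintenance_taken": s.maintenance_taken_sum,
        "maintenance_prescribed": s.maintenance_prescribed_sum,
        "pooled_adherence_pct": s.pooled_adherence_pct,
        "mean_patient_adherence_pct": s.mean_patient_adherence_pct,
        "fully_adherent_days": s.fully_adherent_days,
        "zero_dose_days": s.zero_dose_days,
        "day_denominator": s.day_denominator,
        "fully_adherent_pct": s.fully_adherent_pct,
        "zero_dose_pct": s.zero_dose_pct,
    }


def write_outputs(result: AnalysisResult, out_dir, config: StudyConfig) -> None:
    """Write every pipeline output as delimited text plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    attribution.write_daily_table(result.days_full, out / "daily.csv")
    rows = [_summary_row(result.cohort_summary)] + [
        _summary_row(s) for s in result.regimen_summaries.values()
    ]
    pd.DataFrame(rows).to_csv(out / "adherence_summary.csv", index=False)
    result.per_patient.to_csv(out / "adherence_per_patient.csv", index=False)
    result.weekday.to_csv(out / "weekday_profile.csv")
    result.histogram.to_csv(out / "time_of_day_histogram.csv", index=False)
    result.high_use.by_regimen.to_csv(out / "high_use.csv", index=False)
    result.categories.to_csv(out / "early_adherence_categories.csv", index=False)
    result.survival_table.to_csv(out / "survival.csv", index=False)
    result.km_by_category.to_csv(out / "km_by_category.csv", index=False)
    cohort_stats.write_report(result.report_tables, out)

    manifest = {
        "config": {
            "cutoff_date": config.cutoff_date.isoformat(),
            "min_enrollment_days": config.min_enrollment_days,
            "discontinuation_gap_days": config.discontinuation_gap_days,
            "high_use_threshold": config.high_use_threshold,
            "category_window_days": config.category_window_days,
            "category_cutoffs": list(config.category_cutoffs),
            "ma_window": config.ma_window,
            "adherence_window_days": config.adherence_window_days,
        },
        "n_registry": int(result.inclusion.patients.shape[0] + result.inclusion.exclusions["patient_id"].nunique()),
        "n_included": int(result.inclusion.patients.shape[0]),
        "exclusions": result.inclusion.exclusions["reason"].value_counts().to_dict(),
        "n_events": int(result.inclusion.events.shape[0]),
        "person_days": int(result.high_use.person_days),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
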