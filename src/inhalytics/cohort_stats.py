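"""Group-comparison statistics and demographic/report tables.

The tests mirror the study conventions: one-way ANOVA for continuous
summaries (per-patient mean adherence), the two-sample Wilcoxon rank-sum
for per-patient day proportions between independent regimen arms, Pearson's
chi-square (no continuity correction) for categorical tables, and the
log-rank test for retention curves.  P-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import COARSE_AGE_BAND_LABELS, FINE_AGE_BAND_LABELS, REGIMEN_CODES, age_band
from .metrics import HighUseReport


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    test: str
    groups: pd.DataFrame  # per-group n and summary statistics
    statistic: float
    p_value: float
    flagged: bool = False  # degenerate input (e.g. zero variance)


def wilcoxon_compare(values_a, values_b, metric: str = "") -> GroupComparison:
    """Two-sample Wilcoxon rank-sum on per-patient proportions.

    Exact null distribution when both groups have <=25 observations and no
    ties straddle the groups; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    groups = pd.DataFrame(
        {"n": [len(a), len(b)], "median": [np.median(a), np.median(b)]},
        index=["A", "B"],
    )
    return GroupComparison(
        metric=metric,
        test=f"Wilcoxon rank-sum ({method})",
        groups=groups,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def anova_compare(values_by_group: dict[str, np.ndarray], metric: str = "") -> GroupComparison:
    """One-way ANOVA F test on per-patient means."""
    if len(values_by_group) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = []
    rows = []
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        arrays.append(v)
        rows.append((name, len(v), v.mean(), v.std(ddof=1)))
    groups = pd.DataFrame(rows, columns=["group", "n", "mean", "sd"]).set_index("group")
    pooled = np.concatenate(arrays)
    flagged = bool(np.ptp(pooled) == 0)
    if flagged:
        stat, p = float("nan"), float("nan")
    else:
        res = stats.f_oneway(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        metric=metric, test="one-way ANOVA", groups=groups, statistic=stat,
        p_value=p, flagged=flagged,
    )


def chisq_compare(table: pd.DataFrame | np.ndarray, metric: str = "") -> GroupComparison:
    """Pearson chi-square on a 2-way count table, no continuity correction."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column")
    res = stats.chi2_contingency(counts, correction=False)
    groups = pd.DataFrame(counts) if not isinstance(table, pd.DataFrame) else table
    return GroupComparison(
        metric=metric,
        test=f"chi-square (df={res.dof})",
        groups=groups,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def _count_pct(counts: pd.Series, denominator: int | None = None) -> pd.DataFrame:
    denom = int(counts.sum()) if denominator is None else denominator
    return pd.DataFrame(
        {"n": counts.astype(int), "pct": (100.0 * counts / denom).round(1)}
    )


def build_report(
    patients: pd.DataFrame,
    per_patient_adherence: pd.DataFrame,
    high_use: HighUseReport,
) -> dict[str, pd.DataFrame]:
    """Assemble the demographic, adherence and high-use report tables.

    Patients with missing sex or age are excluded only from the tables
    stratified on the missing variable (the denominator of those tables
    shrinks accordingly, e.g. 3 missing sex in a cohort of 661 gives a sex
    denominator of 658); they stay in every other table.
    """
    if patients.empty:
        raise ValueError("build_report: empty analysis set (missing upstream output?)")
    pats = patients.drop_duplicates("patient_id").copy()
    pats["fine_band"] = pats["age"].map(lambda a: age_band(a if pd.notna(a) else None))
    pats["coarse_band"] = pats["age"].map(lambda a: age_band(a if pd.notna(a) else None, coarse=True))

    tables: dict[str, pd.DataFrame] = {}

    regimen_counts = pats["regimen"].value_counts().reindex(REGIMEN_CODES, fill_value=0)
    tables["regimen"] = _count_pct(regimen_counts)

    known_sex = pats[pats["sex"] != "missing"]
    sex_counts = known_sex["sex"].value_counts().reindex(["female", "male"], fill_value=0)
    tables["sex"] = _count_pct(sex_counts, denominator=len(known_sex))

    known_age = pats.dropna(subset=["fine_band"])
    tables["age_band"] = _count_pct(
        known_age["fine_band"].value_counts().reindex(FINE_AGE_BAND_LABELS, fill_value=0),
        denominator=len(known_age),
    )
    tables["age_group"] = _count_pct(
        known_age["coarse_band"].value_counts().reindex(COARSE_AGE_BAND_LABELS, fill_value=0),
        denominator=len(known_age),
    )

    adh = per_patient_adherence.merge(
        pats[["patient_id", "sex", "coarse_band", "fine_band"]], on="patient_id"
    )

    def _mean_sd(frame: pd.DataFrame, by: str, order) -> pd.DataFrame:
        g = frame.groupby(by)["adherence_pct"].agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        g = g.reindex(order)
        g["mean"] = g["mean"].round(1)
        g["sd"] = g["sd"].round(1)
        return g

    tables["adherence_by_sex"] = _mean_sd(
        adh[adh["sex"] != "missing"], "sex", ["female", "male"]
    )
    tables["adherence_by_age_group"] = _mean_sd(
        adh.dropna(subset=["coarse_band"]), "coarse_band", COARSE_AGE_BAND_LABELS
    )
    tables["adherence_by_age_band"] = _mean_sd(
        adh.dropna(subset=["fine_band"]), "fine_band", FINE_AGE_BAND_LABELS
    )
    tables["adherence_by_regimen"] = _mean_sd(adh, "regimen", REGIMEN_CODES)

    hu = high_use.by_regimen.set_index("regimen").reindex(REGIMEN_CODES)
    n_cohort = len(pats)
    hu_out = pd.DataFrame(
        {
            "patients_n": hu["n_patients_high_use"].fillna(0).astype(int),
            "patients_pct": (100.0 * hu["n_patients_high_use"].fillna(0) / n_cohort).round(2),
            "days_n": hu["n_high_use_days"].fillna(0).astype(int),
            "person_days": hu["person_days"].fillna(0).astype(int),
        }
    )
    hu_out["days_pct"] = (100.0 * hu_out["days_n"] / hu_out["person_days"].replace(0, np.nan)).round(2)
    tables["high_use"] = hu_out
    return tables


def write_report(tables: dict[str, pd.DataFrame], out_dir) -> None:
    """Write each report table as delimited text plus a readable summary."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, table in tables.items():
        table.to_csv(out / f"report_{name}.csv")
        lines.append(f"## {name}\n{table.to_string()}\n")
    (out / "report_summary.txt").write_text("\n".join(lines))
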