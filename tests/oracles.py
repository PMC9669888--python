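"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity from first principles (explicit
risk sets, full permutation enumeration, textbook sum-of-squares) and is
deliberately kept independent of the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def km_product_limit(times, events):
    """Brute-force Kaplan-Meier: explicit product over risk sets.

    Returns ``{event_time: survival_after_time}``; subjects censored at an
    event time stay in that time's risk set (censoring handled after
    events).
    """
    times = np.asarray(times)
    events = np.asarray(events, dtype=bool)
    surv = {}
    s = 1.0
    for t in sorted(set(times[events])):
        n_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_risk
        surv[t] = s
    return surv


def logrank_two_group(times_a, events_a, times_b, events_b):
    """Textbook two-group log-rank chi-square via the O/E table.

    At each pooled event time t: observed events in group A, expected
    n_A(t) * d(t) / n(t), hypergeometric variance.  Statistic is
    (sum(O-E))^2 / sum(V).
    """
    ta, ea = np.asarray(times_a), np.asarray(events_a, dtype=bool)
    tb, eb = np.asarray(times_b), np.asarray(events_b, dtype=bool)
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(all_times[all_events])):
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        n = na + nb
        d = int(((all_times == t) & all_events).sum())
        da = int(((ta == t) & ea).sum())
        o_minus_e += da - na * d / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def rank_sum_exact_p(values_a, values_b):
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Assumes no ties (the U null distribution is then symmetric, so the
    symmetric tail definition used here matches the classical two-sided
    exact p).
    """
    a = list(values_a)
    b = list(values_b)
    pooled = a + b
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    mu = n_a * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = sum(ranks[pooled[i]] for i in combo) - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def anova_f(groups):
    """One-way ANOVA F from the explicit sum-of-squares decomposition."""
    all_vals = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g, dtype=float) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def chisq_pearson(table):
    """Pearson chi-square from the direct formula, no correction."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def retally_events(day_to_minutes: dict[int, list[int]], m: int, n_days: int):
    """Per-event re-tally of the maintenance/reliever split.

    Walks each day's events in clock order, labelling the first ``m`` as
    maintenance; returns total (maintenance, reliever) over days 1..n_days.
    """
    maint = rel = 0
    for day in range(1, n_days + 1):
        events = sorted(day_to_minutes.get(day, []))
        for k, _ in enumerate(events):
            if k < m:
                maint += 1
            else:
                rel += 1
    return maint, rel
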