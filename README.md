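# inhalytics

Adherence analytics for electronically monitored inhaler use.

Smart-inhaler devices clip onto a budesonide/formoterol Turbuhaler and log
the date and time of every actuation. `inhalytics` turns such raw event
logs, together with a regimen registry (1 or 2 inhalations twice daily,
with or without an as-needed reliever component from the same inhaler),
into the standard battery of digital-adherence analyses:

* **dose attribution** — on each calendar day the first *M* recorded
  actuations count as the prescribed maintenance inhalations (*M* = 2 for
  1-BID, 4 for 2-BID regimens); every actuation beyond *M* counts as
  reliever use;
* **adherence metrics** — pooled adherence
  (Σ maintenance taken / Σ maintenance prescribed), the proportion of fully
  adherent days (all *M* inhalations recorded) and of zero-dose days, per
  patient, regimen group and cohort, plus weekday profiles, time-of-day
  histograms, moving-average trend curves and high-use detection
  (>12 actuations/day);
* **retention analysis** — program discontinuation (last recorded dose more
  than 30 days before the data cutoff; otherwise censored at the last dose)
  analysed with Kaplan–Meier curves, log-rank tests and a Cox
  proportional-hazards model (Efron ties) on coarse age bands and the
  low/medium/high early-adherence category from days 1–15
  (cutoffs 70 % and 90 %);
* **a seeded behavioural simulator** — synthetic cohorts with
  Beta-distributed adherence propensity, bimodal morning/evening dose
  times, Friday/weekend adherence dips, rare high-use days and a
  discrete-time dropout hazard (age and early-adherence multipliers, a
  day-30–40 bump), with a truth file for parameter-recovery testing.

## Worked example

```python
import inhalytics as ih

params = ih.SimulationParams(n_patients=120, horizon_days=150, seed=3)
cohort = ih.simulate_cohort(params)
config = params.study_config()          # cutoff at the horizon end
result = ih.run_analysis(cohort.events,
                         cohort.registry.assign(sex=cohort.registry.sex.replace("", "missing")),
                         config)
s = result.cohort_summary
print(s.n_patients, s.pooled_adherence_pct, s.fully_adherent_pct, s.zero_dose_pct)
print(result.logrank_by_category)
```

prints

```
46 74.8 58.7 6.2
LogRankResult(statistic=3.055158564453653, df=2, p_value=0.2170604740025666)
```

i.e. 46 of the 120 simulated patients stayed in the program to day 90 and
enter the analysis set; over days 1–90 they took 74.8 % of prescribed
maintenance inhalations, recorded every prescribed inhalation on 58.7 % of
patient-days and nothing at all on 6.2 % of patient-days; and at this small
n the retention curves of the three early-adherence categories are not yet
significantly separated (log-rank p = 0.22).

The same pipeline is exposed on the command line:

```bash
inhalytics simulate --seed 3 --out data/
inhalytics analyze --events data/events.csv --patients data/registry.csv \
                   --config config.yaml --out out/
inhalytics report --in out/
```

where `config.yaml` sets at least `cutoff_date: 2018-11-11` (all other
keys default: `min_enrollment_days: 90`, `discontinuation_gap_days: 30`,
`high_use_threshold: 12`, `category_window_days: 15`,
`category_cutoffs: [70, 90]`, `ma_window: 5`, `adherence_window_days: 90`).

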