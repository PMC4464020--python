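# registryqc

Data-quality monitoring for population-based maternal and newborn health
registries.

In settings without reliable civil registration, pregnancy registries built
on geographic clusters (each ≈ 300–500 births/year) are often the only
population-based source of stillbirth, neonatal- and maternal-mortality
statistics. Their value depends entirely on data quality, which cannot be
audited against source documents; instead it is monitored with quantitative
indicators compared against pre-defined acceptable values, plus
record-level edit checks. `registryqc` implements that framework end to
end for data managers and biostatisticians running such registries:

* **metric catalogue** — 29 shipped indicators across enrollment,
  pregnancy-outcome, mortality, key-variable and process categories, each
  with its acceptable value (e.g. consent rate > 95%; month-to-month
  enrollment variability, max/min over 6 months, < 2.0; sex ratio
  0.80–1.30; stillbirth : early-neonatal-death ratio 0.50–2.0;
  early : six-week-death ratio 0.60–0.90; ≥ 25 deliveries per
  cluster-month; measured birth weight > 95% of live births; delivery form
  completed < 4 weeks after delivery for > 90%); bounds are overridable in
  a small YAML file, identities are not,
* **metrics engine** — computes every indicator per cluster or per site
  (pooled numerators/denominators, never averaged cluster values) over
  rolling calendar-month windows, returning numerator, denominator, value
  and an `acceptable` / `out_of_range` / `insufficient_data` flag,
* **edit checks** — deterministic range / skip / cross-form /
  missing-expected-form rules that emulate central edit reports, with a
  resolution workflow feeding the critical-edits-addressed indicator,
* **reporting** — monthly cluster/site monitoring reports with
  moving-average trend series, figure-style summary tables, flag and edit
  summaries, plus the seeded ≥ 5% re-keying (double-data-entry) sampling
  list,
* **synthetic registry** — a seeded multi-cluster simulator with realistic
  event timing and an orthogonal defect-injection layer (dropped weights,
  misclassified deaths, missed follow-ups, late data entry, …), so the
  whole pipeline is testable with known ground truth and no real data.

See `docs/methods.md` for the precise definition of every indicator and the
design decisions behind them.

## Worked example

Simulate two years of a 10-cluster registry, compute the site-level
indicators over the final 12 months, and run the edit checks:

```python
from registryqc import (SimulationConfig, simulate_registry,
                        compute_all_metrics, run_checks,
                        DefectConfig, inject_defects)

data = simulate_registry(SimulationConfig(n_clusters=10, months=24, seed=1))
for r in compute_all_metrics(data, "2021-12", span_months=12):
    if r.value is not None:
        print(f"{r.metric_id:24s} {r.value:8.2f}  {r.flag:12s} "
              f"({r.numerator:.0f}/{r.denominator:.0f})"
              if r.denominator is not None else
              f"{r.metric_id:24s} {r.value:8.2f}  {r.flag}")
print("edit items:", len(run_checks(data)))
```

Selected output (site level, window 2021-01…2021-12):

```
consent_rate                99.87  acceptable   (3926/3931)
delivery_outcome           100.00  acceptable   (7409/7409)
followup_outcome            99.68  acceptable   (7156/7179)
sex_ratio                    1.04  acceptable   (2043/1963)
expected_deliveries         75.99  acceptable   (256/337)
sb_end_ratio                 1.19  acceptable   (120/101)
end_sixweek_ratio            0.82  acceptable   (101/123)
bw_measured_live            99.13  acceptable   (3858/3892)
delivery_form_4w            99.98  acceptable   (4039/4040)
edit items: 0
```

Reading the mortality lines: 120 stillbirths against 101 early neonatal
deaths gives a ratio of 1.19, inside the 0.50–2.0 band that screens for
death misclassification; 101 of 123 six-week deaths occurred in the first
week (0.82, inside 0.60–0.90). `expected_deliveries` compares the enrolled
EDD pipeline (256/month over the next six months) with the historical pace
(337/month): 76%, above the 70% early-warning bound for under-enrollment.

Every indicator is inside its acceptable band and the clean extract raises
no edit items — the simulator's defaults are a known-good baseline. Inject
a 30% follow-up failure and the right flag flips:

```python
bad, ledger = inject_defects(data, DefectConfig(drop_followup_record=0.3), seed=2)
r = {m.metric_id: m for m in compute_all_metrics(bad, "2021-12", span_months=12)}
print(r["followup_outcome"].value, r["followup_outcome"].flag)
# 69.68 out_of_range        (vs the >95% acceptable value)
```

The same workflow is available from the shell:

```
registryqc simulate --seed 1 --out data/
registryqc report --data-dir data/ --month 2021-12 --out-dir report/
registryqc edits  --data-dir data/ --out edits.csv
registryqc rekey  --data-dir data/ --month 2021-12 --seed 1 --out rekey.csv
```

## File formats

A registry extract is five comma-separated UTF-8 tables with header rows —
`enrollment.csv`, `delivery.csv`, `births.csv` (one row per infant;
multiple births supported), `followup.csv`, `edits.csv` — with ISO-8601
dates, `true`/`false` booleans and documented categorical levels (see the
column tables in `registryqc.model.TABLE_COLUMNS` and the docstrings in
`registryqc/model.py`). Loading validates every cross-field and cross-table
invariant; offending rows produce row-numbered diagnostics and are never
silently dropped. Metric results are exported as delimited text with
columns `metric_id, category, scope, scope_id, window_start, window_end,
numerator, denominator, value, flag`.

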