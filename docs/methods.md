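# Methods

`registryqc` implements the quantitative data-quality monitoring framework
used by population-based maternal and newborn health registries in
low-resource settings. The monitored system is a set of geographic
*clusters* (catchments of roughly 300–500 births per year) within a *site*;
pregnant women are enrolled during gestation, a pregnancy-outcome (delivery)
form captures each birth, and a six-week postpartum visit ascertains
maternal and infant vital status. Paper forms are completed in the field and
then keyed into a data-management system, so every form carries both a
completion date and a data-entry date. Data quality is monitored not by
auditing against source documents (usually impossible in these settings)
but by a battery of *indicators* — completeness, internal-consistency and
timeliness statistics compared against pre-defined acceptable values — plus
record-level *edit checks*.

## The indicator battery

Twenty-nine indicators are shipped, in five categories. Each is computed per
cluster and per site over a calendar-month window and returned with its
numerator and denominator so a flag can be traced to records.

**Enrollment.** Consent documentation rate (acceptable > 95%), and the
month-to-month enrollment variability factor over the trailing six months —
highest monthly enrollment divided by lowest (< 2.0). A high factor signals
inconsistent case capture.

**Pregnancy outcome.** Proportion of expected delivery outcomes obtained
(> 95%), where a woman is *expected* once her estimated date of delivery
(EDD) plus a 42-day grace period has passed; proportion of due deliveries
with a six-week outcome obtained (> 95%), due 63 days (42 + 21-day grace)
after delivery; the male:female ratio among registered births with known sex
(0.80–1.30); the birth variability factor (< 2.0); the ratio of expected
deliveries (undelivered EDD pipeline over the next six months, as a monthly
rate) to the mean monthly deliveries of the preceding twelve months (> 70%);
and a minimum of 25 deliveries per cluster-month.

**Mortality.** Stillbirth : early-neonatal-death ratio (0.50–2.0) and early
: six-week neonatal death ratio (0.60–0.90). An early neonatal death (END)
is a live birth dying on day of life 0–6; six-week deaths are live births
dying by day 42, so END is a subset and the second ratio is at most 1.
Because both registration failure and misclassification (e.g. an early death
recorded as a stillbirth) move these ratios in characteristic directions,
they are the primary signal for death misclassification. A third rule
requires miscarriages to be internally consistent: gestational age < 20
weeks and weight < 500 g (the stillbirth boundary).

**Key variables.** Measured (scale-weighed) birth-weight proportions for
live births / neonatal deaths / stillbirths (> 95 / 90 / 75%), any-recorded
(measured or estimated) birth-weight proportions (> 99 / 95 / 95%),
conjunctive completeness of maternal anthropometry (> 95%) and of the five
key delivery fields — attendant, location, mode, bag-and-mask use,
gestational age (> 99%) — and birth weight collected within 7 days of birth
(> 95%).

**Process.** Timeliness percentages: enrollment→data entry < 6 weeks
(> 90%), enrollment→EDD > 4 weeks (> 70%), delivery→data entry < 6 weeks
(> 90%), delivery→form completion < 4 weeks (> 90%), form completion→data
entry < 6 weeks (> 90%), delivery→follow-up form within 5–9 weeks (> 80%),
follow-up form→data entry < 6 weeks (> 90%); the birth→weight-record latency
(median days, bound 7); and the proportion of critical edits addressed
(> 80%).

### Encoding decisions

* **Boundary semantics.** Flags are inclusive at the printed bound: a value
  of exactly 95.0 against "> 95%" is acceptable, 1.30 is inside 0.80–1.30.
  Per-record day-gap rules inside the timeliness metrics keep the printed
  strict operator: a 28-day gap fails "< 4 weeks". "Within 7 days" for the
  key-variable birth-weight row is gap ≤ 7. A week is exactly 7 days and
  six weeks is 42 days throughout.
* **Miscarriage consistency** is encoded as "proportion of assessable
  miscarriages consistent with < 20 wk / < 500 g" with lower bound 100:
  the protocol states a per-record rule, so any violation is a data error
  (and also raises a critical edit). Records with either quantity missing
  are unassessable and excluded from the denominator.
* **Weight-record latency** has no printed percentage, only "< 7 days"; it
  is reported as the *median* latency in days, flagged at_most 7. Its
  percentage companion is the within-7-days key-variable indicator.
* **Two delivery-entry timeliness rows** would coincide if "collection of
  delivery information" meant form completion; they are implemented as the
  total latency delivery→data entry and the keying latency form
  completion→data entry respectively, so each monitors a distinct segment.
* **Zero months and the variability factor.** A zero-count month inside a
  variability window makes the max/min ratio infinite; the factor is
  instead returned as undefined (insufficient data) and the zero month is
  surfaced by the minimum-deliveries indicator, which reports value 0 and
  flags out-of-range whenever the cluster has prior delivery history. A
  cluster with no history at all yields insufficient data, so a report for
  an empty cluster contains no spurious out-of-range flags.
* **Windows.** Events are bucketed by their own date (enrollment metrics by
  enrollment date, delivery/birth metrics by delivery date, follow-up
  metrics by the delivery date of the pregnancy). Reports default to a
  six-month rolling window for proportion and ratio indicators — the cadence
  of cluster-level moving-average reports — with the variability factors
  always on six months and the delivery minimum on the report month. The
  span is configurable (12 for annual summaries, 3 for quarterly roll-ups).
* **Pooling.** A site value is always the pooled numerator over pooled
  denominator across its clusters, never a mean of cluster values.
* **Sex ratio** includes stillbirths with known sex (they are registered
  births); infants of unknown sex are excluded from both counts. The
  expected-deliveries indicator is a pace ratio printed as a percent and may
  exceed 100 when the enrollment pipeline outpaces historical deliveries.
* **Loss to follow-up** is an explicit status: a present six-week form whose
  infant statuses are all "lost" does *not* count as an outcome obtained,
  and is distinct from a missing form (which the edit checks flag once the
  visit is 63 days overdue).
* **Grace periods** (42 days past EDD before a delivery is expected, 21
  days past the six-week visit before follow-up is due) are configurable
  defaults; the monitoring protocol does not specify them.

## Edit checks

`run_checks` applies a deterministic, editable rule set: range checks
(gestational age outside 4–46 weeks, birth weight outside 200–6500 g — both
artifact defaults, since the protocol names the check types but not bounds),
a skip check (bag-and-mask answered for a miscarriage-only pregnancy),
cross-form checks (delivery without documented consent; a stillbirth
carrying a day of death; a miscarriage violating the < 20 wk / < 500 g
rule), and missing-expected-form checks (EDD ≥ 42 days past with no
delivery form; delivery ≥ 63 days old with no follow-up form). Each
violation yields one edit item with a stable identifier; output ordering is
deterministic. Missing-form and consistency rules default to *critical*
severity — the class tracked by the > 80%-addressed indicator — and
single-field range violations to noncritical; both the bounds and the
severities can be re-specified per site in a rules file. The missing-form
rules are anchored at an `as_of` date, which for simulated extracts defaults
to the end of the simulated span (the extract's frame of reference) and
otherwise to the latest data-entry date present.

## The synthetic registry

The simulator emulates exactly the structures the indicators consume; it is
the package's test bed, not a demographic model. Per cluster, monthly birth
counts are inhomogeneous Poisson with an annual volume drawn uniformly from
300–500 and sinusoidal seasonality (default amplitude 0.15, site-wide random
phase). Per pregnancy: a miscarriage with probability 0.02 (gestational age
8–19.5 weeks, weight 210–490 g); otherwise term delivery with twin
probability 0.012, per-infant stillbirth probability 0.030, early (day 0–6)
and late (day 7–42) neonatal death probabilities 0.025 and 0.008 among live
births, male probability 0.515, maternal death probability 0.002. These
rates are plausible-for-setting placeholders, not estimates for any real
site. Enrollment precedes the EDD by N(170, 25) days clipped to [42, 238]
(enrollment around 16 weeks gestation, within the protocol's "by 20
weeks"); pregnancies still ongoing at the end of the simulated span appear
as enrollment-only rows and form the expected-deliveries pipeline. Form
latencies are log-normal with medians well inside the process windows
(delivery form 5 d, data entry 7 d, weight measurement 1 d; the follow-up
visit at 42 days plus a capped offset so it stays within 9 weeks).

Defaults are deliberately a *known-good baseline*: a defect-free simulation
passes every indicator and raises zero edit items, which the tests verify at
site scope on pooled 12-month windows. The enrollment lead was chosen so
this holds analytically for the tightest indicator, the expected-deliveries
ratio: E[min(lead, 180 d)]/180 ≈ 0.91 of the six-month pipeline is visible
at the extract date, and the worst seasonal phase scales it by ≈ 0.90, giving
≈ 81% against the 70% bound. Cluster-level monthly windows are *not*
guaranteed all-acceptable — with ~6 stillbirths per cluster-half-year the
mortality ratios are dominated by small-count noise, which is a property of
the real monitoring problem, not of this implementation.

What the simulator does not model: maternal age/parity structure, antenatal
care visits, database snapshotting (a form "exists" regardless of whether
its entry date exceeds the report month), inter-cluster migration, and
secular trends. Passing tests therefore demonstrate that the metrics,
flags, checks and reports behave correctly on data with known ground truth
— not that any particular real registry meets the bounds.

## Defect injection

Eight orthogonal defects corrupt a valid extract at configurable per-record
rates: dropped birth weights, measured weights downgraded to estimates,
early neonatal deaths misclassified as stillbirths (with the tell-tale day
of death removed, so only the ratio metrics can see it), dropped follow-up
records, delayed data entry (+45–90 days), undocumented consent, missed
enrollments (pregnancy first seen at delivery), and blanked key delivery
fields. Selection uses one uniform draw per (record, defect) from a
per-defect substream of the seed, so the records hit at rate r₁ are a subset
of those hit at r₂ ≥ r₁ — each defect's paired indicator degrades *exactly*
monotonically in its rate, which the tests exploit. Every change is recorded
in a ledger that exactly accounts for the input→output difference.

## Numerical and degenerate-input conventions

All latency arithmetic is in whole days on ISO dates. Proportions are
reported on the 0–100 scale at full float precision; exported tables use
`%.10g`. A zero denominator yields an undefined value and an
`insufficient_data` flag, never an exception or an infinity. The re-key
sampling list draws ceil(fraction × forms entered that cluster-month) with a
seeded generator and enforces the 5% protocol floor unless explicitly
overridden. Report exports are bit-stable for a fixed report.

## Problem sizes used in the tests

The shared baseline is 8 clusters × 24 months (≈ 8,000 pregnancies); the
mortality-ratio recovery check uses 20 clusters × 36 months (≈ 24,000
births), chosen so the configured stillbirth:END ratio of 1.25 is estimated
with ≈ 600 stillbirths and a Monte-Carlo SE of ≈ 0.08; the engine-vs-oracle
comparison uses 50 randomized extracts of ≤ 200 records against an
independent per-record brute-force recomputation at 10⁻⁹ tolerance.
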