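"""Indicator computation engine.

Every indicator in the catalogue is computed per cluster or per site over a
calendar-month window, returning a :class:`MetricResult` that exposes its
numerator and denominator so field staff can see exactly which records drove
a flag.

Conventions
-----------
* A window ``AnalysisWindow(as_of, span)`` covers the ``span`` calendar months
  ending at ``as_of`` inclusive.
* Events are bucketed by their own date: enrollment metrics by enrollment
  date, delivery/birth metrics by delivery date, follow-up metrics by the
  delivery date of the matching pregnancy, edits by raised date.
* All day arithmetic is in whole days; a week is exactly 7 days and 6 weeks
  is 42 days.
* Flagging is inclusive at the printed bound (95.0 against "> 95%" is
  acceptable); per-record day-gap rules inside the timeliness metrics use the
  printed strict inequality ("< 4 weeks" means gap <= 27 days).
* Site-level values pool numerators and denominators over clusters; they are
  never means of cluster-level values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalogue import DEFAULT_CATALOGUE, MetricDefinition
from .model import RegistryData

__all__ = [
    "AnalysisWindow",
    "MetricResult",
    "evaluate_flag",
    "variability_factor",
    "consent_rate",
    "enrollment_variability",
    "birth_variability",
    "delivery_outcome_proportion",
    "followup_outcome_proportion",
    "sex_ratio",
    "expected_deliveries_ratio",
    "min_deliveries_check",
    "mortality_ratios",
    "classify_miscarriage",
    "miscarriage_consistency",
    "birthweight_metrics",
    "key_field_completeness",
    "process_timeliness",
    "critical_edits_addressed",
    "compute_all_metrics",
    "filter_cluster",
]

#: days past the EDD before a delivery outcome is considered expected
DELIVERY_GRACE_DAYS = 42
#: days past the 6-week visit (42 d) before a follow-up form is considered due
FOLLOWUP_GRACE_DAYS = 21
#: day-of-life cutoffs
EARLY_NEONATAL_MAX_DAY = 6  # death on day 0-6 = early neonatal death
SIX_WEEK_MAX_DAY = 42


# ---------------------------------------------------------------------------
# windows and results
# ---------------------------------------------------------------------------


def _to_period(month) -> pd.Period:
    if isinstance(month, pd.Period):
        return month.asfreq("M")
    return pd.Period(month, freq="M")


@dataclass(frozen=True)
class AnalysisWindow:
    """``span_months`` calendar months ending at ``as_of_month`` inclusive."""

    as_of_month: object
    span_months: int = 6

    def __post_init__(self) -> None:
        if self.span_months < 1:
            raise ValueError("span_months must be positive")
        object.__setattr__(self, "as_of_month", _to_period(self.as_of_month))

    @property
    def end(self) -> pd.Period:
        return self.as_of_month

    @property
    def start(self) -> pd.Period:
        return self.as_of_month - (self.span_months - 1)

    @property
    def start_date(self) -> pd.Timestamp:
        return self.start.to_timestamp(how="start")

    @property
    def end_date(self) -> pd.Timestamp:
        return self.end.to_timestamp(how="end").normalize()

    def months(self) -> list[pd.Period]:
        return list(pd.period_range(self.start, self.end, freq="M"))

    def contains(self, dates: pd.Series) -> pd.Series:
        p = dates.dt.to_period("M")
        return dates.notna() & (p >= self.start) & (p <= self.end)


@dataclass(frozen=True)
class MetricResult:
    metric_id: str
    scope: str  # 'cluster' | 'site'
    scope_id: str
    window_start: str  # 'YYYY-MM'
    window_end: str
    numerator: float | None
    denominator: float | None
    value: float | None
    flag: str  # 'acceptable' | 'out_of_range' | 'insufficient_data'

    def as_dict(self) -> dict:
        return {
            "metric_id": self.metric_id,
            "scope": self.scope,
            "scope_id": self.scope_id,
            "window_start": self.window_start,
            "window_end": self.window_end,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "value": self.value,
            "flag": self.flag,
        }


def evaluate_flag(value: float | None, definition: MetricDefinition) -> str:
    """Flag a metric value against its acceptable bound(s), inclusively."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "insufficient_data"
    sem = definition.bound_semantics
    if sem in ("at_least", "exact_minimum"):
        ok = value >= definition.lower_bound
    elif sem == "at_most":
        ok = value <= definition.upper_bound
    elif sem == "within_range":
        ok = definition.lower_bound <= value <= definition.upper_bound
    else:  # pragma: no cover - catalogue validated
        raise ValueError(sem)
    return "acceptable" if ok else "out_of_range"


def _result(
    metric_id: str,
    window: AnalysisWindow,
    numerator: float | None,
    denominator: float | None,
    value: float | None,
    *,
    scope: str = "site",
    scope_id: str = "all",
    catalogue: dict[str, MetricDefinition] | None = None,
) -> MetricResult:
    defn = (catalogue or DEFAULT_CATALOGUE)[metric_id]
    if value is not None and isinstance(value, float) and math.isnan(value):
        value = None
    flag = evaluate_flag(value, defn)
    return MetricResult(
        metric_id=metric_id,
        scope=scope,
        scope_id=scope_id,
        window_start=str(window.start),
        window_end=str(window.end),
        numerator=None if numerator is None else float(numerator),
        denominator=None if denominator is None else float(denominator),
        value=None if value is None else float(value),
        flag=flag,
    )


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


# ---------------------------------------------------------------------------
# record plumbing
# ---------------------------------------------------------------------------


def filter_cluster(data: RegistryData, cluster_id: str) -> RegistryData:
    """Restrict a registry extract to one cluster (links followed by study_id)."""
    enr = data.enrollment[data.enrollment["cluster_id"] == cluster_id]
    dlv = data.delivery[data.delivery["cluster_id"] == cluster_id]
    ids = set(enr["study_id"]) | set(dlv["study_id"])
    return RegistryData(
        enrollment=enr.reset_index(drop=True),
        delivery=dlv.reset_index(drop=True),
        births=data.births[data.births["study_id"].isin(ids)].reset_index(drop=True),
        followup=data.followup[data.followup["study_id"].isin(ids)].reset_index(drop=True),
        edits=data.edits[data.edits["study_id"].isin(ids)].reset_index(drop=True),
        meta=dict(data.meta),
    )


def _births_with_delivery(births: pd.DataFrame, delivery: pd.DataFrame) -> pd.DataFrame:
    """Births joined to the delivery date of their pregnancy."""
    return births.merge(
        delivery[["study_id", "delivery_date"]], on="study_id", how="inner"
    )


def _monthly_counts(dates: pd.Series, window: AnalysisWindow) -> list[int]:
    p = dates.dropna().dt.to_period("M")
    return [int((p == m).sum()) for m in window.months()]


# ---------------------------------------------------------------------------
# enrollment metrics
# ---------------------------------------------------------------------------


def consent_rate(enrollment: pd.DataFrame, window: AnalysisWindow, **scope) -> MetricResult:
    """Proportion of subjects enrolled in the window with consent documented."""
    in_w = window.contains(enrollment["enrollment_date"])
    den = int(in_w.sum())
    num = int((in_w & enrollment["consent_obtained"]).sum())
    return _result("consent_rate", window, num, den, _pct(num, den), **scope)


def variability_factor(monthly_counts: Sequence[int]) -> float | None:
    """Highest monthly count divided by lowest, over exactly 6 months.

    Returns None (insufficient data) when any month's count is zero: the
    ratio is kept numeric and a zero month is surfaced by the per-month
    minimum-deliveries indicator instead.
    """
    if len(monthly_counts) != 6:
        raise ValueError("variability factor requires exactly 6 monthly counts")
    counts = [int(c) for c in monthly_counts]
    if min(counts) <= 0:
        return None
    return max(counts) / min(counts)


def _variability_metric(
    metric_id: str, dates: pd.Series, window: AnalysisWindow, **scope
) -> MetricResult:
    w6 = AnalysisWindow(window.end, 6)
    counts = _monthly_counts(dates, w6)
    first = dates.dropna().dt.to_period("M").min() if dates.notna().any() else None
    if first is None or first > w6.start:
        # fewer than 6 months of history
        return _result(metric_id, w6, None, None, None, **scope)
    value = variability_factor(counts)
    num = max(counts) if value is not None else None
    den = min(counts) if value is not None else None
    return _result(metric_id, w6, num, den, value, **scope)


def enrollment_variability(enrollment: pd.DataFrame, window: AnalysisWindow, **scope) -> MetricResult:
    return _variability_metric("enroll_variability", enrollment["enrollment_date"], window, **scope)


def birth_variability(delivery: pd.DataFrame, window: AnalysisWindow, **scope) -> MetricResult:
    return _variability_metric("birth_variability", delivery["delivery_date"], window, **scope)


# ---------------------------------------------------------------------------
# pregnancy outcome metrics
# ---------------------------------------------------------------------------


def delivery_outcome_proportion(
    enrollment: pd.DataFrame,
    delivery: pd.DataFrame,
    window: AnalysisWindow,
    *,
    grace_days: int = DELIVERY_GRACE_DAYS,
    **scope,
) -> MetricResult:
    """Proportion of expected delivery outcomes obtained.

    Expected = consented enrollments whose EDD plus a grace period has passed
    by the window end; obtained = a delivery (pregnancy-outcome) form exists.
    """
    due = enrollment["edd"] + pd.Timedelta(days=grace_days)
    expected = enrollment["consent_obtained"] & enrollment["edd"].notna() & (due <= window.end_date)
    den = int(expected.sum())
    have = enrollment["study_id"].isin(set(delivery["study_id"]))
    num = int((expected & have).sum())
    return _result("delivery_outcome", window, num, den, _pct(num, den), **scope)


def followup_outcome_proportion(
    delivery: pd.DataFrame,
    followup: pd.DataFrame,
    window: AnalysisWindow,
    *,
    grace_days: int = FOLLOWUP_GRACE_DAYS,
    **scope,
) -> MetricResult:
    """Proportion of due deliveries with a 6-week outcome obtained.

    Due = delivery date + 42 days + grace has passed by the window end.
    Obtained = a follow-up record exists whose infant statuses are not all
    'lost' (loss to follow-up is an explicit status, not an absent form).
    """
    due_date = delivery["delivery_date"] + pd.Timedelta(days=SIX_WEEK_MAX_DAY + grace_days)
    due = delivery["delivery_date"].notna() & (due_date <= window.end_date)
    den = int(due.sum())
    fup = followup.copy()
    statuses = fup["infant_status_42d"].astype(str).str.split("|")
    obtained_ids = set(fup.loc[statuses.map(lambda xs: any(s != "lost" for s in xs)), "study_id"])
    num = int((due & delivery["study_id"].isin(obtained_ids)).sum())
    return _result("followup_outcome", window, num, den, _pct(num, den), **scope)


def sex_ratio(
    births: pd.DataFrame, delivery: pd.DataFrame, window: AnalysisWindow, **scope
) -> MetricResult:
    """Male:female ratio among live and stillborn infants with known sex."""
    b = _births_with_delivery(births, delivery)
    b = b[window.contains(b["delivery_date"]) & b["status"].isin(["live_birth", "stillbirth"])]
    males = int((b["sex"] == "male").sum())
    females = int((b["sex"] == "female").sum())
    value = None if females == 0 else males / females
    return _result("sex_ratio", window, males, females, value, **scope)


def expected_deliveries_ratio(
    enrollment: pd.DataFrame,
    delivery: pd.DataFrame,
    as_of_month,
    *,
    horizon_months: int = 6,
    history_months: int = 12,
    **scope,
) -> MetricResult:
    """EDD pipeline over the next 6 months vs the historical delivery pace.

    Numerator: enrolled, consented, undelivered women with an EDD in the next
    ``horizon_months`` months, divided by the horizon length (a monthly rate).
    Denominator: mean monthly deliveries over the preceding ``history_months``
    calendar months ending at ``as_of_month``.  Reported as a percentage.
    """
    as_of = _to_period(as_of_month)
    window = AnalysisWindow(as_of, 1)
    ddates = delivery["delivery_date"].dropna()
    if ddates.empty:
        return _result("expected_deliveries", window, None, None, None, **scope)
    first = ddates.dt.to_period("M").min()
    if (as_of - first).n + 1 < 6:  # needs at least 6 months of delivery history
        return _result("expected_deliveries", window, None, None, None, **scope)

    hist = AnalysisWindow(as_of, history_months)
    n_hist = int(hist.contains(delivery["delivery_date"]).sum())
    mean_monthly = n_hist / history_months
    if mean_monthly == 0:
        return _result("expected_deliveries", window, None, None, None, **scope)

    future_start = as_of + 1
    future_end = as_of + horizon_months
    edd_p = enrollment["edd"].dt.to_period("M")
    undelivered = ~enrollment["study_id"].isin(set(delivery["study_id"]))
    pipeline = (
        enrollment["consent_obtained"]
        & undelivered
        & enrollment["edd"].notna()
        & (edd_p >= future_start)
        & (edd_p <= future_end)
    )
    monthly_expected = int(pipeline.sum()) / horizon_months
    value = 100.0 * monthly_expected / mean_monthly
    return _result("expected_deliveries", window, monthly_expected, mean_monthly, value, **scope)


def min_deliveries_check(delivery: pd.DataFrame, month, **scope) -> MetricResult:
    """Delivery count for one calendar month against the per-cluster minimum.

    A zero month in a cluster with prior delivery history is a real finding
    (value 0, out of range); a cluster with no history up to the month yields
    insufficient data.
    """
    m = _to_period(month)
    window = AnalysisWindow(m, 1)
    p = delivery["delivery_date"].dropna().dt.to_period("M")
    if p.empty or p.min() > m:
        return _result("min_deliveries", window, None, None, None, **scope)
    count = int((p == m).sum())
    return _result("min_deliveries", window, count, None, float(count), **scope)


# ---------------------------------------------------------------------------
# mortality metrics
# ---------------------------------------------------------------------------


def mortality_ratios(
    births: pd.DataFrame,
    followup: pd.DataFrame,
    delivery: pd.DataFrame,
    window: AnalysisWindow,
    **scope,
) -> tuple[MetricResult, MetricResult]:
    """Stillbirth:END ratio and END:6-week-death ratio for the window.

    Early neonatal deaths (END) are live births dying on day of life 0-6;
    six-week deaths are live births dying by day 42 (END is a subset).
    Undefined on a zero denominator.
    """
    b = _births_with_delivery(births, delivery)
    b = b[window.contains(b["delivery_date"])]
    stillbirths = int((b["status"] == "stillbirth").sum())
    live = b["status"] == "live_birth"
    dd = b["death_day_of_life"]
    end = int((live & dd.notna() & (dd <= EARLY_NEONATAL_MAX_DAY)).sum())
    sixweek = int((live & dd.notna() & (dd <= SIX_WEEK_MAX_DAY)).sum())
    r1 = _result(
        "sb_end_ratio", window, stillbirths, end,
        None if end == 0 else stillbirths / end, **scope,
    )
    r2 = _result(
        "end_sixweek_ratio", window, end, sixweek,
        None if sixweek == 0 else end / sixweek, **scope,
    )
    return r1, r2


def classify_miscarriage(birth_row, delivery_row) -> str:
    """Classify one miscarriage as consistent / inconsistent / unassessable.

    Consistent means gestational age < 20 weeks AND birth weight < 500 g
    (measured or estimated); unassessable when either quantity is missing.
    """
    status = birth_row["status"] if isinstance(birth_row, (dict, pd.Series)) else birth_row.status
    if status != "miscarriage":
        raise ValueError("classify_miscarriage called on a non-miscarriage birth")
    ga = delivery_row["gestational_age_weeks"]
    wt = birth_row["birth_weight_grams"]
    if pd.isna(ga) or pd.isna(wt):
        return "unassessable"
    return "consistent" if (ga < 20 and wt < 500) else "inconsistent"


def miscarriage_consistency(
    births: pd.DataFrame, delivery: pd.DataFrame, window: AnalysisWindow, **scope
) -> MetricResult:
    """Proportion of assessable miscarriages consistent with <20 wk / <500 g."""
    b = births.merge(
        delivery[["study_id", "delivery_date", "gestational_age_weeks"]],
        on="study_id", how="inner",
    )
    b = b[(b["status"] == "miscarriage") & window.contains(b["delivery_date"])]
    assessable = b["gestational_age_weeks"].notna() & b["birth_weight_grams"].notna()
    consistent = assessable & (b["gestational_age_weeks"] < 20) & (b["birth_weight_grams"] < 500)
    den = int(assessable.sum())
    num = int(consistent.sum())
    return _result("miscarriage_consistency", window, num, den, _pct(num, den), **scope)


# ---------------------------------------------------------------------------
# key-variable metrics
# ---------------------------------------------------------------------------


def birthweight_metrics(
    births: pd.DataFrame,
    followup: pd.DataFrame,
    delivery: pd.DataFrame,
    window: AnalysisWindow,
    **scope,
) -> tuple[list[MetricResult], dict[str, float]]:
    """Measured / any-recorded birth-weight proportions by outcome class.

    Classes: live births, neonatal deaths (live births dying by day 42, a
    subset of live births), and stillbirths.  Also returns the three-way
    source breakdown (measured / estimated / missing, percentages summing to
    100) over live and stillborn infants in the window.
    """
    b = _births_with_delivery(births, delivery)
    b = b[window.contains(b["delivery_date"])]
    live = b["status"] == "live_birth"
    neod = live & b["death_day_of_life"].notna() & (b["death_day_of_life"] <= SIX_WEEK_MAX_DAY)
    sb = b["status"] == "stillbirth"
    measured = b["birth_weight_source"] == "measured"
    anyw = b["birth_weight_source"].isin(["measured", "estimated"])

    results = []
    for mid, cls in (
        ("bw_measured_live", live),
        ("bw_measured_neodeath", neod),
        ("bw_measured_stillbirth", sb),
    ):
        den, num = int(cls.sum()), int((cls & measured).sum())
        results.append(_result(mid, window, num, den, _pct(num, den), **scope))
    for mid, cls in (
        ("bw_any_live", live),
        ("bw_any_neodeath", neod),
        ("bw_any_stillbirth", sb),
    ):
        den, num = int(cls.sum()), int((cls & anyw).sum())
        results.append(_result(mid, window, num, den, _pct(num, den), **scope))

    registered = live | sb
    n = int(registered.sum())
    if n == 0:
        breakdown = {"measured": float("nan"), "estimated": float("nan"), "missing": float("nan")}
    else:
        breakdown = {
            "measured": 100.0 * int((registered & measured).sum()) / n,
            "estimated": 100.0 * int((registered & (b["birth_weight_source"] == "estimated")).sum()) / n,
            "missing": 100.0 * int((registered & (b["birth_weight_source"] == "missing")).sum()) / n,
        }
    return results, breakdown


def key_field_completeness(
    enrollment: pd.DataFrame,
    delivery: pd.DataFrame,
    births: pd.DataFrame,
    window: AnalysisWindow,
    **scope,
) -> tuple[MetricResult, MetricResult]:
    """Conjunctive completeness of maternal anthropometry and delivery fields.

    A record counts complete only when every named field is non-missing.
    For pregnancies whose only outcomes are miscarriages, bag-and-mask use is
    not expected (it is a skip field) and is exempt from the delivery rule.
    """
    in_w = window.contains(enrollment["enrollment_date"])
    den_a = int(in_w.sum())
    complete_a = (
        enrollment["maternal_height_recorded"]
        & enrollment["maternal_weight_recorded"]
        & enrollment["anthropometry_timing_recorded"]
    )
    num_a = int((in_w & complete_a).sum())
    r_anthro = _result("anthro_complete", window, num_a, den_a, _pct(num_a, den_a), **scope)

    in_w_d = window.contains(delivery["delivery_date"])
    den_d = int(in_w_d.sum())
    non_misc = births[births["status"] != "miscarriage"]["study_id"]
    misc_only = ~delivery["study_id"].isin(set(non_misc)) & delivery["study_id"].isin(
        set(births["study_id"])
    )
    complete_d = (
        (delivery["delivery_attendant"] != "missing")
        & (delivery["delivery_location"] != "missing")
        & (delivery["delivery_mode"] != "missing")
        & ((delivery["bag_and_mask_used"] != "missing") | misc_only)
        & delivery["gestational_age_weeks"].notna()
    )
    num_d = int((in_w_d & complete_d).sum())
    r_deliv = _result("delivery_fields_complete", window, num_d, den_d, _pct(num_d, den_d), **scope)
    return r_anthro, r_deliv


# ---------------------------------------------------------------------------
# process metrics
# ---------------------------------------------------------------------------


def _gap_days(later: pd.Series, earlier: pd.Series) -> pd.Series:
    return (later - earlier).dt.days.astype(float)


def process_timeliness(
    data: RegistryData, window: AnalysisWindow, **scope
) -> tuple[list[MetricResult], dict[str, int]]:
    """The nine timeliness/latency indicators for the window.

    Each proportion metric counts eligible records whose day-gap satisfies the
    printed strict inequality ("between 5 and 9 weeks" is the closed interval
    [35, 63] days).  Records with either date missing are excluded from the
    denominator and tallied in the returned missing-date companion dict.
    ``weight_record_latency`` is a days-valued metric: the median latency from
    birth to a recorded weight.
    """
    enr, dlv, fup = data.enrollment, data.delivery, data.followup
    results: list[MetricResult] = []
    missing: dict[str, int] = {}

    def prop_metric(mid: str, in_window: pd.Series, gaps: pd.Series, compliant: pd.Series) -> None:
        eligible = in_window & gaps.notna()
        missing[mid] = int((in_window & gaps.isna()).sum())
        den = int(eligible.sum())
        num = int((eligible & compliant).sum())
        results.append(_result(mid, window, num, den, _pct(num, den), **scope))

    # birth -> weight recorded (days metric, median)
    b = _births_with_delivery(data.births, dlv)
    b = b[window.contains(b["delivery_date"]) & b["status"].isin(["live_birth", "stillbirth"])]
    wgap = _gap_days(b["weight_record_date"], b["delivery_date"])
    missing["weight_record_latency"] = int(wgap.isna().sum())
    have = wgap.dropna()
    results.append(
        _result(
            "weight_record_latency", window, None, float(len(have)),
            None if have.empty else float(have.median()), **scope,
        )
    )

    # enrollment-based
    in_e = window.contains(enr["enrollment_date"])
    g = _gap_days(enr["enrollment_data_entry_date"], enr["enrollment_date"])
    prop_metric("enroll_entry_6w", in_e, g, g < 42)
    g = _gap_days(enr["edd"], enr["enrollment_date"])
    prop_metric("enroll_edd_4w", in_e, g, g > 28)

    # delivery-based
    in_d = window.contains(dlv["delivery_date"])
    g = _gap_days(dlv["delivery_data_entry_date"], dlv["delivery_date"])
    prop_metric("delivery_info_entry_6w", in_d, g, g < 42)
    g = _gap_days(dlv["delivery_form_completion_date"], dlv["delivery_date"])
    prop_metric("delivery_form_4w", in_d, g, g < 28)
    g = _gap_days(dlv["delivery_data_entry_date"], dlv["delivery_form_completion_date"])
    prop_metric("form_entry_6w", in_d, g, g < 42)

    # follow-up based (windowed by delivery date of the pregnancy)
    f = fup.merge(dlv[["study_id", "delivery_date"]], on="study_id", how="inner")
    in_f = window.contains(f["delivery_date"])
    g = _gap_days(f["followup_form_completion_date"], f["delivery_date"])
    prop_metric("followup_form_5_9w", in_f, g, (g >= 35) & (g <= 63))
    g = _gap_days(f["followup_data_entry_date"], f["followup_form_completion_date"])
    prop_metric("followup_entry_6w", in_f, g, g < 42)

    # birth weight within 7 days (key-variable row, percentage form)
    in_b = window.contains(b["delivery_date"])
    prop_metric("bw_within_7d", pd.Series(True, index=b.index), wgap, wgap <= 7)

    return results, missing


def critical_edits_addressed(edits: pd.DataFrame, window: AnalysisWindow, **scope) -> MetricResult:
    """Proportion of critical edits raised in the window that are addressed."""
    crit = (edits["severity"] == "critical") & window.contains(edits["raised_date"])
    den = int(crit.sum())
    num = int((crit & (edits["status"] == "addressed")).sum())
    return _result("critical_edits", window, num, den, _pct(num, den), **scope)


# ---------------------------------------------------------------------------
# catalogue-wide driver
# ---------------------------------------------------------------------------


def compute_all_metrics(
    data: RegistryData,
    as_of_month,
    *,
    span_months: int = 6,
    scope: str = "site",
    scope_id: str = "all",
    catalogue: dict[str, MetricDefinition] | None = None,
) -> list[MetricResult]:
    """Compute every catalogue indicator for one scope and window.

    ``span_months`` governs the rolling window of the proportion/ratio
    metrics; the variability factors always use a 6-month window and the
    minimum-deliveries indicator always uses the single ``as_of`` month, as
    the protocol specifies.  When ``scope='cluster'``, ``data`` must already
    be restricted to that cluster (see :func:`filter_cluster`).
    """
    window = AnalysisWindow(as_of_month, span_months)
    sc = {"scope": scope, "scope_id": scope_id, "catalogue": catalogue}
    results: list[MetricResult] = []
    results.append(consent_rate(data.enrollment, window, **sc))
    results.append(enrollment_variability(data.enrollment, window, **sc))
    results.append(delivery_outcome_proportion(data.enrollment, data.delivery, window, **sc))
    results.append(followup_outcome_proportion(data.delivery, data.followup, window, **sc))
    results.append(sex_ratio(data.births, data.delivery, window, **sc))
    results.append(birth_variability(data.delivery, window, **sc))
    results.append(expected_deliveries_ratio(data.enrollment, data.delivery, window.end, **sc))
    results.append(min_deliveries_check(data.delivery, window.end, **sc))
    results.extend(mortality_ratios(data.births, data.followup, data.delivery, window, **sc))
    results.append(miscarriage_consistency(data.births, data.delivery, window, **sc))
    bw, _ = birthweight_metrics(data.births, data.followup, data.delivery, window, **sc)
    results.extend(bw)
    results.extend(key_field_completeness(data.enrollment, data.delivery, data.births, window, **sc))
    proc, _ = process_timeliness(data, window, **sc)
    results.extend(proc)
    results.append(critical_edits_addressed(data.edits, window, **sc))

    cat = catalogue or DEFAULT_CATALOGUE
    order = {mid: i for i, mid in enumerate(cat)}
    results.sort(key=lambda r: order[r.metric_id])
    return results


def results_frame(results: Iterable[MetricResult], catalogue=None) -> pd.DataFrame:
    """MetricResults as the documented delimited-text table."""
    cat = catalogue or DEFAULT_CATALOGUE
    rows = []
    for r in results:
        d = r.as_dict()
        d["category"] = cat[r.metric_id].category
        rows.append(d)
    cols = [
        "metric_id", "category", "scope", "scope_id", "window_start",
        "window_end", "numerator", "denominator", "value", "flag",
    ]
    return pd.DataFrame(rows, columns=cols)
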