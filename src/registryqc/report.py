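"""Monitoring-report assembly, trend series, and the re-key sampling list.

A monitoring report bundles, for one scope (a cluster or the whole site) and
one report month:

* one :class:`~registryqc.metrics.MetricResult` per catalogue indicator,
* a trailing moving-average series per indicator (the pooled rolling-window
  value at each of the last six months),
* summary tables mirroring the figures a data-coordinating centre circulates:
  yearly delivery-outcome percentages, per-cluster monthly birth counts,
  the distribution of cluster stillbirth:END ratios over the categories
  {<0.5, 0.5-2.0, >2.0}, the birth-weight source breakdown by year, and the
  yearly delivery-form timeliness percentage,
* flag and edit summaries.

Site-level values pool numerators and denominators over clusters.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogue import DEFAULT_CATALOGUE, MetricDefinition
from .metrics import (
    AnalysisWindow,
    MetricResult,
    birthweight_metrics,
    compute_all_metrics,
    delivery_outcome_proportion,
    filter_cluster,
    mortality_ratios,
    process_timeliness,
    results_frame,
)
from .model import RegistryData

__all__ = ["MonitoringReport", "build_report", "rekey_sample", "export_report"]

MOVING_AVERAGE_MONTHS = 6


@dataclass
class MonitoringReport:
    scope: str
    scope_id: str
    report_month: str
    metrics: pd.DataFrame  # one row per catalogue indicator
    moving_averages: pd.DataFrame  # metric_id x month rolling values
    series: dict[str, pd.DataFrame]  # figure-style summary tables
    flag_summary: dict[str, int]
    edit_summary: pd.DataFrame
    meta: dict = field(default_factory=dict)


def _year_windows(data: RegistryData) -> list[tuple[int, AnalysisWindow]]:
    dates = data.delivery["delivery_date"].dropna()
    if dates.empty:
        return []
    years = sorted(dates.dt.year.unique())
    return [(int(y), AnalysisWindow(pd.Period(f"{y}-12", freq="M"), 12)) for y in years]


def _figure_series(data: RegistryData, month: pd.Period) -> dict[str, pd.DataFrame]:
    """The figure-style summary tables, over the whole data span."""
    series: dict[str, pd.DataFrame] = {}

    # yearly delivery-outcome % (site)
    rows = []
    for year, w in _year_windows(data):
        r = delivery_outcome_proportion(data.enrollment, data.delivery, w)
        rows.append({"year": year, "value_pct": r.value,
                     "numerator": r.numerator, "denominator": r.denominator})
    series["delivery_outcome_by_year"] = pd.DataFrame(
        rows, columns=["year", "value_pct", "numerator", "denominator"])

    # per-cluster monthly births over the trailing 6 months
    w6 = AnalysisWindow(month, MOVING_AVERAGE_MONTHS)
    rows = []
    dlv = data.delivery
    for cluster in sorted(dlv["cluster_id"].dropna().unique()):
        sub = dlv.loc[dlv["cluster_id"] == cluster, "delivery_date"].dropna()
        p = sub.dt.to_period("M")
        for mth in w6.months():
            rows.append({"cluster_id": cluster, "month": str(mth), "births": int((p == mth).sum())})
    series["monthly_births_by_cluster"] = pd.DataFrame(rows, columns=["cluster_id", "month", "births"])

    # stillbirth:END ratio categories across clusters, by year
    rows = []
    clusters = sorted(data.delivery["cluster_id"].dropna().unique())
    for year, w in _year_windows(data):
        cats = {"<0.5": 0, "0.5-2.0": 0, ">2.0": 0, "undefined": 0}
        for cluster in clusters:
            sub = filter_cluster(data, cluster)
            r1, _ = mortality_ratios(sub.births, sub.followup, sub.delivery, w)
            if r1.value is None:
                cats["undefined"] += 1
            elif r1.value < 0.5:
                cats["<0.5"] += 1
            elif r1.value <= 2.0:
                cats["0.5-2.0"] += 1
            else:
                cats[">2.0"] += 1
        n = max(len(clusters), 1)
        rows.append({"year": year, **{f"pct_{k}": 100.0 * v / n for k, v in cats.items()}})
    series["sb_end_categories_by_year"] = pd.DataFrame(rows)

    # birth-weight source breakdown by year (site)
    rows = []
    for year, w in _year_windows(data):
        _, breakdown = birthweight_metrics(data.births, data.followup, data.delivery, w)
        rows.append({"year": year, **{f"pct_{k}": v for k, v in breakdown.items()}})
    series["bw_source_by_year"] = pd.DataFrame(rows)

    # delivery-form timeliness (< 4 weeks) by year (site)
    rows = []
    for year, w in _year_windows(data):
        proc, _ = process_timeliness(data, w)
        r = next(x for x in proc if x.metric_id == "delivery_form_4w")
        rows.append({"year": year, "value_pct": r.value,
                     "numerator": r.numerator, "denominator": r.denominator})
    series["delivery_form_timeliness_by_year"] = pd.DataFrame(
        rows, columns=["year", "value_pct", "numerator", "denominator"])

    return series


def build_report(
    data: RegistryData,
    scope: str,
    month,
    *,
    scope_id: str = "all",
    span_months: int = 6,
    catalogue: dict[str, MetricDefinition] | None = None,
) -> MonitoringReport:
    """Assemble the monitoring report for one scope and report month.

    ``scope`` is ``'site'`` (all clusters pooled) or ``'cluster'`` (pass the
    cluster in ``scope_id``).  ``span_months`` is the rolling window of the
    proportion/ratio indicators (default six months, the cadence of the
    cluster-level moving-average reports); variability factors always use six
    months and the minimum-deliveries indicator the report month itself.

    Raises ValueError for a month outside the data span.
    """
    month = pd.Period(month, freq="M")
    cat = catalogue or DEFAULT_CATALOGUE

    all_dates = pd.concat([
        data.enrollment["enrollment_date"], data.delivery["delivery_date"],
    ]).dropna()
    if not all_dates.empty:
        lo, hi = all_dates.dt.to_period("M").min(), all_dates.dt.to_period("M").max()
        if month < lo or month > hi:
            raise ValueError(f"report month {month} outside data span [{lo}, {hi}]")

    if scope == "cluster":
        scoped = filter_cluster(data, scope_id)
    elif scope == "site":
        scoped = data
    else:
        raise ValueError("scope must be 'site' or 'cluster'")

    results = compute_all_metrics(
        scoped, month, span_months=span_months, scope=scope, scope_id=scope_id, catalogue=cat
    )
    metrics = results_frame(results, cat)

    # trailing moving-average series: pooled rolling value at each month
    ma_rows = []
    for k in range(MOVING_AVERAGE_MONTHS - 1, -1, -1):
        m = month - k
        if not all_dates.empty and m < lo:
            continue
        for r in compute_all_metrics(
            scoped, m, span_months=span_months, scope=scope, scope_id=scope_id, catalogue=cat
        ):
            ma_rows.append({"metric_id": r.metric_id, "month": str(m), "value": r.value, "flag": r.flag})
    moving_averages = pd.DataFrame(ma_rows, columns=["metric_id", "month", "value", "flag"])

    flags = metrics["flag"].value_counts().to_dict()
    flag_summary = {k: int(flags.get(k, 0)) for k in ("acceptable", "out_of_range", "insufficient_data")}

    ed = scoped.edits
    if len(ed):
        edit_summary = (
            ed.groupby(["severity", "status"]).size().rename("count").reset_index()
        )
    else:
        edit_summary = pd.DataFrame(columns=["severity", "status", "count"])

    return MonitoringReport(
        scope=scope,
        scope_id=scope_id,
        report_month=str(month),
        metrics=metrics,
        moving_averages=moving_averages,
        series=_figure_series(scoped, month),
        flag_summary=flag_summary,
        edit_summary=edit_summary,
        meta={"span_months": span_months, **{k: v for k, v in data.meta.items() if k != "diagnostics"}},
    )


def rekey_sample(
    data: RegistryData,
    month,
    *,
    fraction: float = 0.05,
    seed: int = 0,
    allow_below_minimum: bool = False,
) -> pd.DataFrame:
    """Random double-data-entry (re-keying) sampling list for one month.

    For each cluster and form type, draws a seeded uniform random sample of
    ``ceil(fraction x forms entered that month)`` study IDs.  The protocol
    floor is 5%; a smaller fraction is rejected unless explicitly overridden.
    """
    if fraction < 0.05 and not allow_below_minimum:
        raise ValueError("re-key fraction below the 5% protocol minimum; "
                         "pass allow_below_minimum=True to override")
    month = pd.Period(month, freq="M")
    rng = np.random.default_rng(seed)

    cluster_of = pd.concat([
        data.enrollment.set_index("study_id")["cluster_id"],
        data.delivery.set_index("study_id")["cluster_id"],
    ])
    cluster_of = cluster_of[~cluster_of.index.duplicated()]

    forms = []
    for form, df, col in (
        ("enrollment", data.enrollment, "enrollment_data_entry_date"),
        ("delivery", data.delivery, "delivery_data_entry_date"),
        ("followup", data.followup, "followup_data_entry_date"),
    ):
        entered = df[df[col].dt.to_period("M") == month]
        for sid in entered["study_id"]:
            forms.append({"form": form, "study_id": sid, "cluster_id": cluster_of.get(sid, "")})
    frame = pd.DataFrame(forms, columns=["form", "study_id", "cluster_id"])

    picks = []
    for cluster, group in frame.sort_values(["cluster_id", "form", "study_id"]).groupby("cluster_id", sort=True):
        n = math.ceil(fraction * len(group))
        idx = rng.choice(len(group), size=n, replace=False)
        picks.append(group.iloc[np.sort(idx)])
    if not picks:
        return pd.DataFrame(columns=["form", "study_id", "cluster_id", "month"])
    out = pd.concat(picks, ignore_index=True)
    out["month"] = str(month)
    return out


def export_report(report: MonitoringReport, outdir, *, fmt: str = "delimited") -> dict[str, str]:
    """Write a report as delimited text plus a JSON metadata sidecar.

    Output is bit-stable for a fixed report.  Returns name→path of files.
    """
    if fmt not in ("delimited", "structured-text"):
        raise ValueError("fmt must be 'delimited' or 'structured-text'")
    os.makedirs(outdir, exist_ok=True)
    sep = "," if fmt == "delimited" else "\t"
    ext = "csv" if fmt == "delimited" else "tsv"
    paths: dict[str, str] = {}

    def put(name: str, df: pd.DataFrame) -> None:
        p = os.path.join(outdir, f"{name}.{ext}")
        df.to_csv(p, sep=sep, index=False, float_format="%.10g")
        paths[name] = p

    put("metrics", report.metrics)
    put("moving_averages", report.moving_averages)
    put("edit_summary", report.edit_summary)
    for name, df in report.series.items():
        put(f"series_{name}", df)
    flag_df = pd.DataFrame(
        [{"flag": k, "count": v} for k, v in sorted(report.flag_summary.items())]
    )
    put("flag_summary", flag_df)

    meta = {
        "scope": report.scope,
        "scope_id": report.scope_id,
        "report_month": report.report_month,
        **{k: v for k, v in sorted(report.meta.items()) if isinstance(v, (str, int, float, bool))},
    }
    mpath = os.path.join(outdir, "report_meta.json")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["report_meta"] = mpath
    return paths
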