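"""Independent brute-force recomputation of every indicator.

Deliberately written as per-record Python loops over plain dicts — filter,
count, divide — sharing no code with the engine, so the two routes can be
compared on arbitrary fixtures.  Returns (numerator, denominator, value)
triples keyed by metric id, with None marking an undefined value.
"""

import calendar
from statistics import median

import pandas as pd


def _ym(ts):
    return (ts.year, ts.month)


def _add_months(ym, k):
    t = ym[0] * 12 + (ym[1] - 1) + k
    return (t // 12, t % 12 + 1)


def _last_day(ym):
    return pd.Timestamp(ym[0], ym[1], calendar.monthrange(*ym)[1])


def _in_win(ts, start, end):
    return pd.notna(ts) and start <= _ym(ts) <= end


def _months_between(a, b):
    """Number of month steps from a to b (b - a)."""
    return (b[0] * 12 + b[1]) - (a[0] * 12 + a[1])


def oracle_all(data, as_of: str, span: int) -> dict:
    """Recompute the full indicator battery by brute force."""
    end = _ym(pd.Period(as_of, freq="M").to_timestamp())
    start = _add_months(end, -(span - 1))
    end_date = _last_day(end)

    enr = data.enrollment.to_dict("records")
    dlv = data.delivery.to_dict("records")
    bir = data.births.to_dict("records")
    fup = data.followup.to_dict("records")
    edt = data.edits.to_dict("records")

    out = {}

    def ratio(num, den, scale=1.0):
        return None if den == 0 else scale * num / den

    # --- consent rate ---
    in_w = [e for e in enr if _in_win(e["enrollment_date"], start, end)]
    num = sum(1 for e in in_w if e["consent_obtained"])
    out["consent_rate"] = (num, len(in_w), ratio(num, len(in_w), 100.0))

    # --- variability factors (always a 6-month window ending at as_of) ---
    def variability(dates, mid):
        v_start = _add_months(end, -5)
        dates = [d for d in dates if pd.notna(d)]
        if not dates or _ym(min(dates)) > v_start:
            out[mid] = (None, None, None)
            return
        counts = []
        for k in range(6):
            m = _add_months(v_start, k)
            counts.append(sum(1 for d in dates if _ym(d) == m))
        if min(counts) <= 0:
            out[mid] = (None, None, None)
        else:
            out[mid] = (max(counts), min(counts), max(counts) / min(counts))

    variability([e["enrollment_date"] for e in enr], "enroll_variability")
    variability([d["delivery_date"] for d in dlv], "birth_variability")

    # --- delivery outcome obtained ---
    dlv_ids = {d["study_id"] for d in dlv}
    expected = [
        e for e in enr
        if e["consent_obtained"] and pd.notna(e["edd"])
        and e["edd"] + pd.Timedelta(days=42) <= end_date
    ]
    num = sum(1 for e in expected if e["study_id"] in dlv_ids)
    out["delivery_outcome"] = (num, len(expected), ratio(num, len(expected), 100.0))

    # --- follow-up outcome obtained ---
    obtained = {
        f["study_id"] for f in fup
        if any(s != "lost" for s in str(f["infant_status_42d"]).split("|"))
    }
    due = [
        d for d in dlv
        if pd.notna(d["delivery_date"]) and d["delivery_date"] + pd.Timedelta(days=63) <= end_date
    ]
    num = sum(1 for d in due if d["study_id"] in obtained)
    out["followup_outcome"] = (num, len(due), ratio(num, len(due), 100.0))

    # helper: births joined to a delivery date
    ddate = {d["study_id"]: d["delivery_date"] for d in dlv}
    joined = [
        {**b, "delivery_date": ddate[b["study_id"]]} for b in bir if b["study_id"] in ddate
    ]
    in_bw = [b for b in joined if _in_win(b["delivery_date"], start, end)]

    # --- sex ratio ---
    reg = [b for b in in_bw if b["status"] in ("live_birth", "stillbirth")]
    males = sum(1 for b in reg if b["sex"] == "male")
    females = sum(1 for b in reg if b["sex"] == "female")
    out["sex_ratio"] = (males, females, ratio(males, females))

    # --- expected deliveries vs historical pace ---
    d_dates = [d["delivery_date"] for d in dlv if pd.notna(d["delivery_date"])]
    if not d_dates or _months_between(_ym(min(d_dates)), end) + 1 < 6:
        out["expected_deliveries"] = (None, None, None)
    else:
        hist_start = _add_months(end, -11)
        n_hist = sum(1 for d in d_dates if hist_start <= _ym(d) <= end)
        mean_monthly = n_hist / 12
        if mean_monthly == 0:
            out["expected_deliveries"] = (None, None, None)
        else:
            f_start, f_end = _add_months(end, 1), _add_months(end, 6)
            pipeline = sum(
                1 for e in enr
                if e["consent_obtained"] and e["study_id"] not in dlv_ids
                and pd.notna(e["edd"]) and f_start <= _ym(e["edd"]) <= f_end
            )
            out["expected_deliveries"] = (
                pipeline / 6, mean_monthly, 100.0 * (pipeline / 6) / mean_monthly
            )

    # --- minimum deliveries in the as_of month ---
    if not d_dates or _ym(min(d_dates)) > end:
        out["min_deliveries"] = (None, None, None)
    else:
        c = sum(1 for d in d_dates if _ym(d) == end)
        out["min_deliveries"] = (c, None, float(c))

    # --- mortality ratios ---
    sb = sum(1 for b in in_bw if b["status"] == "stillbirth")
    end_deaths = sum(
        1 for b in in_bw
        if b["status"] == "live_birth" and pd.notna(b["death_day_of_life"])
        and b["death_day_of_life"] <= 6
    )
    sixw = sum(
        1 for b in in_bw
        if b["status"] == "live_birth" and pd.notna(b["death_day_of_life"])
        and b["death_day_of_life"] <= 42
    )
    out["sb_end_ratio"] = (sb, end_deaths, ratio(sb, end_deaths))
    out["end_sixweek_ratio"] = (end_deaths, sixw, ratio(end_deaths, sixw))

    # --- miscarriage consistency ---
    ga_of = {d["study_id"]: d["gestational_age_weeks"] for d in dlv}
    misc = [b for b in in_bw if b["status"] == "miscarriage"]
    assessable = [
        b for b in misc
        if pd.notna(ga_of.get(b["study_id"])) and pd.notna(b["birth_weight_grams"])
    ]
    consistent = sum(
        1 for b in assessable
        if ga_of[b["study_id"]] < 20 and b["birth_weight_grams"] < 500
    )
    out["miscarriage_consistency"] = (
        consistent, len(assessable), ratio(consistent, len(assessable), 100.0)
    )

    # --- birth-weight metrics ---
    live = [b for b in in_bw if b["status"] == "live_birth"]
    neod = [b for b in live if pd.notna(b["death_day_of_life"]) and b["death_day_of_life"] <= 42]
    sbs = [b for b in in_bw if b["status"] == "stillbirth"]
    for mid, cls in (
        ("bw_measured_live", live), ("bw_measured_neodeath", neod), ("bw_measured_stillbirth", sbs),
    ):
        num = sum(1 for b in cls if b["birth_weight_source"] == "measured")
        out[mid] = (num, len(cls), ratio(num, len(cls), 100.0))
    for mid, cls in (
        ("bw_any_live", live), ("bw_any_neodeath", neod), ("bw_any_stillbirth", sbs),
    ):
        num = sum(1 for b in cls if b["birth_weight_source"] in ("measured", "estimated"))
        out[mid] = (num, len(cls), ratio(num, len(cls), 100.0))

    # --- key-field completeness ---
    in_e = [e for e in enr if _in_win(e["enrollment_date"], start, end)]
    num = sum(
        1 for e in in_e
        if e["maternal_height_recorded"] and e["maternal_weight_recorded"]
        and e["anthropometry_timing_recorded"]
    )
    out["anthro_complete"] = (num, len(in_e), ratio(num, len(in_e), 100.0))

    has_birth = {b["study_id"] for b in bir}
    non_misc = {b["study_id"] for b in bir if b["status"] != "miscarriage"}
    in_d = [d for d in dlv if _in_win(d["delivery_date"], start, end)]
    num = 0
    for d in in_d:
        misc_only = d["study_id"] in has_birth and d["study_id"] not in non_misc
        if (
            d["delivery_attendant"] != "missing"
            and d["delivery_location"] != "missing"
            and d["delivery_mode"] != "missing"
            and (d["bag_and_mask_used"] != "missing" or misc_only)
            and pd.notna(d["gestational_age_weeks"])
        ):
            num += 1
    out["delivery_fields_complete"] = (num, len(in_d), ratio(num, len(in_d), 100.0))

    # --- process metrics ---
    def gap(a, b):
        if pd.isna(a) or pd.isna(b):
            return None
        return (a - b).days

    def prop(mid, pairs, pred):
        gaps = [gap(a, b) for a, b in pairs]
        gaps = [g for g in gaps if g is not None]
        num = sum(1 for g in gaps if pred(g))
        out[mid] = (num, len(gaps), ratio(num, len(gaps), 100.0))

    wgaps = [
        gap(b["weight_record_date"], b["delivery_date"])
        for b in in_bw if b["status"] in ("live_birth", "stillbirth")
    ]
    have = [g for g in wgaps if g is not None]
    out["weight_record_latency"] = (None, float(len(have)), median(have) if have else None)

    prop("enroll_entry_6w",
         [(e["enrollment_data_entry_date"], e["enrollment_date"]) for e in in_e],
         lambda g: g < 42)
    prop("enroll_edd_4w", [(e["edd"], e["enrollment_date"]) for e in in_e], lambda g: g > 28)
    prop("delivery_info_entry_6w",
         [(d["delivery_data_entry_date"], d["delivery_date"]) for d in in_d],
         lambda g: g < 42)
    prop("delivery_form_4w",
         [(d["delivery_form_completion_date"], d["delivery_date"]) for d in in_d],
         lambda g: g < 28)
    prop("form_entry_6w",
         [(d["delivery_data_entry_date"], d["delivery_form_completion_date"]) for d in in_d],
         lambda g: g < 42)
    in_f = [
        {**f, "delivery_date": ddate[f["study_id"]]}
        for f in fup if f["study_id"] in ddate
    ]
    in_f = [f for f in in_f if _in_win(f["delivery_date"], start, end)]
    prop("followup_form_5_9w",
         [(f["followup_form_completion_date"], f["delivery_date"]) for f in in_f],
         lambda g: 35 <= g <= 63)
    prop("followup_entry_6w",
         [(f["followup_data_entry_date"], f["followup_form_completion_date"]) for f in in_f],
         lambda g: g < 42)
    prop("bw_within_7d",
         [(b["weight_record_date"], b["delivery_date"])
          for b in in_bw if b["status"] in ("live_birth", "stillbirth")],
         lambda g: g <= 7)

    # --- critical edits addressed ---
    crit = [
        e for e in edt
        if e["severity"] == "critical" and _in_win(e["raised_date"], start, end)
    ]
    num = sum(1 for e in crit if e["status"] == "addressed")
    out["critical_edits"] = (num, len(crit), ratio(num, len(crit), 100.0))

    return out
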