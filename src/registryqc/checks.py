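"""Edit-check engine: range, skip, cross-form and missing-expected-form checks.

Mirrors the central edit reports of a registry data-coordinating centre:
deterministic rules applied to the record collections, each violation
yielding one edit item in the ``edits.csv`` schema.  The default rule set
covers out-of-range values, skip-pattern violations, cross-form
inconsistencies (including the miscarriage gestational-age/weight rule) and
study IDs where a delivery or follow-up form was expected but has not been
entered.

Default range bounds and severity assignments are editable: rules can be
loaded from a YAML file so a site can re-specify them.  By default,
missing-expected-form rules and mortality-consistency rules are critical;
single-field range violations are noncritical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .metrics import DELIVERY_GRACE_DAYS, FOLLOWUP_GRACE_DAYS, SIX_WEEK_MAX_DAY
from .model import RegistryData, empty_table

__all__ = ["CheckRule", "default_rules", "load_rules", "run_checks", "resolve_edits"]


@dataclass(frozen=True)
class CheckRule:
    rule_id: str
    form: str  # enrollment | delivery | followup
    field_name: str
    check_type: str  # range | skip | cross_form | missing_expected_form
    severity: str  # critical | noncritical
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.check_type not in {"range", "skip", "cross_form", "missing_expected_form"}:
            raise ValueError(f"unknown check_type {self.check_type!r}")
        if self.severity not in {"critical", "noncritical"}:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.check_type == "range" and not {"min", "max"} <= set(self.params):
            raise ValueError(f"range rule {self.rule_id} needs min/max params")


def default_rules() -> list[CheckRule]:
    """The shipped rule set (bounds are editable site policy, not protocol)."""
    return [
        CheckRule("ga_range", "delivery", "gestational_age_weeks", "range",
                  "noncritical", {"min": 4.0, "max": 46.0}),
        CheckRule("bw_range", "delivery", "birth_weight_grams", "range",
                  "noncritical", {"min": 200.0, "max": 6500.0}),
        CheckRule("bag_mask_miscarriage", "delivery", "bag_and_mask_used", "skip",
                  "noncritical", {"governing_field": "status", "trigger_value": "miscarriage"}),
        CheckRule("stillbirth_death_day", "delivery", "death_day_of_life", "cross_form",
                  "critical"),
        CheckRule("delivery_without_consent", "delivery", "consent_obtained", "cross_form",
                  "noncritical"),
        CheckRule("miscarriage_inconsistent", "delivery", "gestational_age_weeks", "cross_form",
                  "critical", {"max_ga_weeks": 20.0, "max_weight_grams": 500.0}),
        CheckRule("missing_delivery_form", "delivery", "delivery_date", "missing_expected_form",
                  "critical", {"grace_days": DELIVERY_GRACE_DAYS}),
        CheckRule("missing_followup_form", "followup", "followup_form_completion_date",
                  "missing_expected_form", "critical",
                  {"horizon_days": SIX_WEEK_MAX_DAY + FOLLOWUP_GRACE_DAYS}),
    ]


def load_rules(path) -> list[CheckRule]:
    """Load a rule set from a YAML list of CheckRule mappings."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or []
    return [CheckRule(**r) for r in raw]


_KNOWN_FIELDS = {
    "gestational_age_weeks", "birth_weight_grams", "bag_and_mask_used",
    "death_day_of_life", "consent_obtained", "delivery_date",
    "followup_form_completion_date",
}


def run_checks(
    data: RegistryData,
    rules: list[CheckRule] | None = None,
    *,
    as_of: pd.Timestamp | str | None = None,
) -> pd.DataFrame:
    """Apply the rules; return edit items in the ``edits.csv`` schema.

    ``as_of`` anchors the missing-expected-form rules and becomes the raised
    date of every item; it defaults to the latest data-entry date present.
    Output ordering is stable: by (study_id, rule_id, infant key).  A clean
    dataset yields an empty frame.
    """
    rules = default_rules() if rules is None else rules
    for rule in rules:
        if rule.field_name not in _KNOWN_FIELDS:
            raise ValueError(f"rule {rule.rule_id} references unknown field {rule.field_name!r}")

    if as_of is None and data.meta.get("end_month"):
        # simulated extracts are "as of" the end of their simulated span
        as_of = pd.Period(data.meta["end_month"], freq="M").to_timestamp(how="end").normalize()
    if as_of is None:
        candidates = [
            data.enrollment["enrollment_data_entry_date"].max() if len(data.enrollment) else pd.NaT,
            data.delivery["delivery_data_entry_date"].max() if len(data.delivery) else pd.NaT,
            data.followup["followup_data_entry_date"].max() if len(data.followup) else pd.NaT,
        ]
        candidates = [c for c in candidates if pd.notna(c)]
        as_of = max(candidates) if candidates else pd.Timestamp("1970-01-01")
    as_of = pd.Timestamp(as_of)

    enr, dlv, bir, fup = data.enrollment, data.delivery, data.births, data.followup
    items: list[dict] = []

    def emit(rule: CheckRule, study_id: str, key: str = "") -> None:
        suffix = f":{key}" if key else ""
        items.append({
            "edit_id": f"{rule.rule_id}:{study_id}{suffix}",
            "study_id": study_id,
            "form": rule.form,
            "field_name": rule.field_name,
            "check_type": rule.check_type,
            "severity": rule.severity,
            "status": "open",
            "raised_date": as_of,
            "resolved_date": pd.NaT,
        })

    misc_ids = set(bir.loc[bir["status"] == "miscarriage", "study_id"])
    births_ga = bir.merge(dlv[["study_id", "gestational_age_weeks"]], on="study_id", how="left")

    for rule in rules:
        if rule.rule_id == "ga_range" or (
            rule.check_type == "range" and rule.field_name == "gestational_age_weeks"
        ):
            ga = dlv["gestational_age_weeks"]
            bad = ga.notna() & ((ga < rule.params["min"]) | (ga > rule.params["max"]))
            for sid in dlv.loc[bad, "study_id"]:
                emit(rule, sid)
        elif rule.check_type == "range" and rule.field_name == "birth_weight_grams":
            wt = bir["birth_weight_grams"]
            bad = wt.notna() & ((wt < rule.params["min"]) | (wt > rule.params["max"]))
            for _, row in bir.loc[bad].iterrows():
                emit(rule, row["study_id"], str(row["infant_index"]))
        elif rule.check_type == "skip" and rule.field_name == "bag_and_mask_used":
            # skip rule: bag-and-mask must be blank when the governing outcome
            # is a miscarriage-only pregnancy
            bad = dlv["study_id"].isin(misc_ids) & (dlv["bag_and_mask_used"] != "missing")
            non_misc = set(bir.loc[bir["status"] != "miscarriage", "study_id"])
            bad &= ~dlv["study_id"].isin(non_misc)
            for sid in dlv.loc[bad, "study_id"]:
                emit(rule, sid)
        elif rule.rule_id == "stillbirth_death_day" or (
            rule.check_type == "cross_form" and rule.field_name == "death_day_of_life"
        ):
            bad = (bir["status"] == "stillbirth") & bir["death_day_of_life"].notna()
            for _, row in bir.loc[bad].iterrows():
                emit(rule, row["study_id"], str(row["infant_index"]))
        elif rule.check_type == "cross_form" and rule.field_name == "consent_obtained":
            consented = set(enr.loc[enr["consent_obtained"], "study_id"])
            bad = ~dlv["study_id"].isin(consented)
            for sid in dlv.loc[bad, "study_id"]:
                emit(rule, sid)
        elif rule.rule_id == "miscarriage_inconsistent":
            m = births_ga[births_ga["status"] == "miscarriage"]
            assessable = m["gestational_age_weeks"].notna() & m["birth_weight_grams"].notna()
            bad = assessable & (
                (m["gestational_age_weeks"] >= rule.params["max_ga_weeks"])
                | (m["birth_weight_grams"] >= rule.params["max_weight_grams"])
            )
            for _, row in m.loc[bad].iterrows():
                emit(rule, row["study_id"], str(row["infant_index"]))
        elif rule.rule_id == "missing_delivery_form":
            due = enr["edd"] + pd.Timedelta(days=int(rule.params["grace_days"]))
            bad = (
                enr["consent_obtained"]
                & enr["edd"].notna()
                & (due < as_of)
                & ~enr["study_id"].isin(set(dlv["study_id"]))
            )
            for sid in enr.loc[bad, "study_id"]:
                emit(rule, sid)
        elif rule.rule_id == "missing_followup_form":
            due = dlv["delivery_date"] + pd.Timedelta(days=int(rule.params["horizon_days"]))
            bad = (due <= as_of) & ~dlv["study_id"].isin(set(fup["study_id"]))
            for sid in dlv.loc[bad, "study_id"]:
                emit(rule, sid)
        else:  # pragma: no cover - guarded by _KNOWN_FIELDS
            raise ValueError(f"rule {rule.rule_id} not implemented")

    if not items:
        return empty_table("edits")
    out = pd.DataFrame(items)
    out = out.sort_values(["study_id", "edit_id"], kind="mergesort").reset_index(drop=True)
    return out


def resolve_edits(
    edits: pd.DataFrame,
    resolutions,
    resolved_date: pd.Timestamp | str,
) -> pd.DataFrame:
    """Mark the listed edit_ids addressed; idempotent on already-addressed items.

    Raises KeyError for an unknown edit_id.
    """
    out = edits.copy()
    ids = list(resolutions)
    known = set(out["edit_id"])
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise KeyError(f"unknown edit_id(s): {unknown[:5]}")
    mask = out["edit_id"].isin(ids) & (out["status"] != "addressed")
    out.loc[mask, "status"] = "addressed"
    out.loc[mask, "resolved_date"] = pd.Timestamp(resolved_date)
    return out
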