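"""Orthogonal data-quality defect injection.

Each defect corrupts one aspect of an otherwise-valid registry extract at a
configured per-record rate, emulating the failure modes a monitoring system
must detect: unweighed newborns, estimated rather than measured weights,
early neonatal deaths misrecorded as stillbirths, missed follow-up visits,
slow data entry, undocumented consent, pregnancies first seen at delivery,
and incomplete delivery forms.

Defects are independent and composable; corruption always manifests as
missing / misdated / misclassified values, never as structurally malformed
rows.  Selection uses one uniform draw per (record, defect) from a
per-defect substream of the seed, so the set of records hit at rate ``r1``
is a subset of the set hit at ``r2 >= r1`` — degradation of the paired
indicator is exactly monotone in the rate, not just in expectation.

Every change is recorded in a defect ledger (table, record key, defect name)
that exactly accounts for the difference between the input and output
collections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .model import RegistryData

__all__ = ["DefectConfig", "inject_defects", "DEFECT_METRIC_MAP"]

#: which catalogue indicator each defect knob primarily degrades
DEFECT_METRIC_MAP = {
    "drop_birth_weight": "bw_measured_live",
    "downgrade_measured_to_estimated": "bw_measured_live",
    "misclassify_end_as_stillbirth": "sb_end_ratio",
    "drop_followup_record": "followup_outcome",
    "delay_data_entry": "form_entry_6w",
    "drop_consent_flag": "consent_rate",
    "miss_enrollment": "expected_deliveries",
    "drop_key_delivery_fields": "delivery_fields_complete",
}

_DEFECTS = tuple(DEFECT_METRIC_MAP)


@dataclass(frozen=True)
class DefectConfig:
    """Per-defect application rates in [0, 1]; all default to 0 (no defect)."""

    drop_birth_weight: float = 0.0
    downgrade_measured_to_estimated: float = 0.0
    misclassify_end_as_stillbirth: float = 0.0
    drop_followup_record: float = 0.0
    delay_data_entry: float = 0.0
    drop_consent_flag: float = 0.0
    miss_enrollment: float = 0.0
    drop_key_delivery_fields: float = 0.0
    # added-days distribution for delay_data_entry (uniform integer range)
    delay_days_min: int = 45
    delay_days_max: int = 90

    def __post_init__(self) -> None:
        for name in _DEFECTS:
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} rate must be in [0, 1], got {rate}")
        if not 0 < self.delay_days_min <= self.delay_days_max:
            raise ValueError("delay day range must be positive and non-empty")

    @classmethod
    def from_yaml(cls, path) -> "DefectConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _select(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Coupled Bernoulli selection: record i is hit iff u_i < rate."""
    return rng.random(n) < rate


def inject_defects(
    data: RegistryData, defects: DefectConfig, seed: int
) -> tuple[RegistryData, pd.DataFrame]:
    """Apply each configured defect; return (corrupted data, defect ledger).

    The ledger has columns (defect, table, study_id, record_key), one row per
    corrupted record.  With all rates at zero the output equals the input and
    the ledger is empty.
    """
    out = data.copy()
    ledger_rows: list[dict] = []

    def log(defect: str, table: str, study_ids, keys) -> None:
        for sid, key in zip(study_ids, keys):
            ledger_rows.append(
                {"defect": defect, "table": table, "study_id": sid, "record_key": key}
            )

    streams = {
        name: np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        for i, name in enumerate(_DEFECTS)
    }

    # --- drop_birth_weight: weight never obtained ---
    bir = out.births
    eligible = bir["birth_weight_source"] != "missing"
    hit = _select(streams["drop_birth_weight"], len(bir), defects.drop_birth_weight) & eligible.to_numpy()
    if hit.any():
        bir.loc[hit, "birth_weight_grams"] = np.nan
        bir.loc[hit, "birth_weight_source"] = "missing"
        bir.loc[hit, "weight_record_date"] = pd.NaT
        keys = bir.loc[hit, "study_id"] + ":" + bir.loc[hit, "infant_index"].astype(str)
        log("drop_birth_weight", "births", bir.loc[hit, "study_id"], keys)

    # --- downgrade_measured_to_estimated ---
    eligible = (out.births["birth_weight_source"] == "measured").to_numpy()
    hit = _select(
        streams["downgrade_measured_to_estimated"], len(out.births),
        defects.downgrade_measured_to_estimated,
    ) & eligible
    if hit.any():
        out.births.loc[hit, "birth_weight_source"] = "estimated"
        keys = out.births.loc[hit, "study_id"] + ":" + out.births.loc[hit, "infant_index"].astype(str)
        log("downgrade_measured_to_estimated", "births", out.births.loc[hit, "study_id"], keys)

    # --- misclassify_end_as_stillbirth ---
    bir = out.births
    eligible = (
        (bir["status"] == "live_birth")
        & bir["death_day_of_life"].notna()
        & (bir["death_day_of_life"] <= 6)
    ).to_numpy()
    hit = _select(
        streams["misclassify_end_as_stillbirth"], len(bir),
        defects.misclassify_end_as_stillbirth,
    ) & eligible
    if hit.any():
        bir.loc[hit, "status"] = "stillbirth"
        bir.loc[hit, "death_day_of_life"] = np.nan
        keys = bir.loc[hit, "study_id"] + ":" + bir.loc[hit, "infant_index"].astype(str)
        log("misclassify_end_as_stillbirth", "births", bir.loc[hit, "study_id"], keys)

    # --- drop_followup_record ---
    fup = out.followup
    hit = _select(streams["drop_followup_record"], len(fup), defects.drop_followup_record)
    if hit.any():
        log("drop_followup_record", "followup", fup.loc[hit, "study_id"], fup.loc[hit, "study_id"])
        out.followup = fup.loc[~hit].reset_index(drop=True)

    # --- delay_data_entry: shift entry dates on all three form types ---
    # selection uniforms are drawn for all tables before any delay amounts so
    # that selection stays coupled across rates
    rng_delay = streams["delay_data_entry"]
    tables_cols = (
        ("enrollment", "enrollment_data_entry_date"),
        ("delivery", "delivery_data_entry_date"),
        ("followup", "followup_data_entry_date"),
    )
    hits = {t: _select(rng_delay, len(out.table(t)), defects.delay_data_entry) for t, _ in tables_cols}
    for table, col in tables_cols:
        df = out.table(table)
        hit = hits[table]
        if hit.any():
            extra = rng_delay.integers(defects.delay_days_min, defects.delay_days_max + 1, size=int(hit.sum()))
            df.loc[hit, col] = df.loc[hit, col] + pd.to_timedelta(extra, unit="D")
            log("delay_data_entry", table, df.loc[hit, "study_id"], df.loc[hit, "study_id"])

    # --- drop_consent_flag ---
    enr = out.enrollment
    eligible = enr["consent_obtained"].to_numpy()
    hit = _select(streams["drop_consent_flag"], len(enr), defects.drop_consent_flag) & eligible
    if hit.any():
        enr.loc[hit, "consent_obtained"] = False
        log("drop_consent_flag", "enrollment", enr.loc[hit, "study_id"], enr.loc[hit, "study_id"])

    # --- miss_enrollment: pregnancy first appears at delivery ---
    enr = out.enrollment
    hit = _select(streams["miss_enrollment"], len(enr), defects.miss_enrollment)
    if hit.any():
        log("miss_enrollment", "enrollment", enr.loc[hit, "study_id"], enr.loc[hit, "study_id"])
        out.enrollment = enr.loc[~hit].reset_index(drop=True)

    # --- drop_key_delivery_fields ---
    dlv = out.delivery
    hit = _select(streams["drop_key_delivery_fields"], len(dlv), defects.drop_key_delivery_fields)
    if hit.any():
        dlv.loc[hit, "delivery_attendant"] = "missing"
        dlv.loc[hit, "delivery_location"] = "missing"
        dlv.loc[hit, "delivery_mode"] = "missing"
        dlv.loc[hit, "bag_and_mask_used"] = "missing"
        dlv.loc[hit, "gestational_age_weeks"] = np.nan
        log("drop_key_delivery_fields", "delivery", dlv.loc[hit, "study_id"], dlv.loc[hit, "study_id"])

    ledger = pd.DataFrame(ledger_rows, columns=["defect", "table", "study_id", "record_key"])
    out.meta["defect_seed"] = seed
    out.meta["defect_config"] = dataclasses.asdict(defects)
    return out, ledger
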