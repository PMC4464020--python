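import numpy as np
import pandas as pd
import pytest

from registryqc import RegistryData, SimulationConfig, simulate_registry
from registryqc.model import TABLE_COLUMNS, empty_table

# ---------------------------------------------------------------------------
# typed-frame builders for hand-made fixtures
# ---------------------------------------------------------------------------

_DATE_COLS = {
    col
    for cols in TABLE_COLUMNS.values()
    for col, kind in cols.items()
    if kind in ("date", "odate")
}

_DEFAULTS = {
    "enrollment": {
        "cluster_id": "C01",
        "consent_obtained": True,
        "enrollment_date": "2021-01-10",
        "edd": "2021-06-20",
        "maternal_height_recorded": True,
        "maternal_weight_recorded": True,
        "anthropometry_timing_recorded": True,
        "enrollment_form_completion_date": "2021-01-11",
        "enrollment_data_entry_date": "2021-01-18",
    },
    "delivery": {
        "cluster_id": "C01",
        "delivery_date": "2021-06-18",
        "delivery_location": "health_center",
        "delivery_attendant": "nurse_midwife",
        "delivery_mode": "vaginal",
        "bag_and_mask_used": "no",
        "gestational_age_weeks": 39.0,
        "delivery_form_completion_date": "2021-06-21",
        "delivery_data_entry_date": "2021-06-28",
    },
    "births": {
        "infant_index": 1,
        "status": "live_birth",
        "sex": "male",
        "birth_weight_grams": 3000.0,
        "birth_weight_source": "measured",
        "weight_record_date": None,
        "death_day_of_life": None,
    },
    "followup": {
        "followup_form_completion_date": "2021-08-02",
        "followup_data_entry_date": "2021-08-09",
        "infant_status_42d": "alive",
        "maternal_status_42d": "alive",
    },
    "edits": {
        "form": "delivery",
        "field_name": "gestational_age_weeks",
        "check_type": "range",
        "severity": "noncritical",
        "status": "open",
        "raised_date": "2021-06-30",
        "resolved_date": None,
    },
}


def typed_frame(name: str, rows: list[dict]) -> pd.DataFrame:
    """Build a typed table from partial row dicts, filling schema defaults."""
    if not rows:
        return empty_table(name)
    full = [{**_DEFAULTS[name], **r} for r in rows]
    df = pd.DataFrame(full, columns=list(TABLE_COLUMNS[name]))
    for col, kind in TABLE_COLUMNS[name].items():
        if kind in ("date", "odate"):
            df[col] = pd.to_datetime(df[col])
        elif kind == "bool":
            df[col] = df[col].astype(bool)
        elif kind in ("ofloat", "oint"):
            df[col] = pd.to_numeric(df[col]).astype(float)
        elif kind == "int":
            df[col] = df[col].astype("int64")
    return df


def make_registry(
    enrollment=(), delivery=(), births=(), followup=(), edits=()
) -> RegistryData:
    return RegistryData(
        enrollment=typed_frame("enrollment", list(enrollment)),
        delivery=typed_frame("delivery", list(delivery)),
        births=typed_frame("births", list(births)),
        followup=typed_frame("followup", list(followup)),
        edits=typed_frame("edits", list(edits)),
    )


# ---------------------------------------------------------------------------
# randomized (but schema- and invariant-valid) small fixtures
# ---------------------------------------------------------------------------


def random_registry(seed: int, max_pregnancies: int = 50) -> RegistryData:
    """A small random registry extract exercising missing values, miscarriages,
    deaths, loss to follow-up and out-of-window latencies."""
    rng = np.random.default_rng(seed)
    base = pd.Timestamp("2020-06-01")
    enr_rows, dlv_rows, bir_rows, fup_rows, edit_rows = [], [], [], [], []
    n = int(rng.integers(0, max_pregnancies + 1))
    for i in range(n):
        sid = f"S{i:04d}"
        cluster = f"C{int(rng.integers(1, 4)):02d}"
        e_date = base + pd.Timedelta(days=int(rng.integers(0, 480)))
        consent = rng.random() < 0.9
        edd = e_date + pd.Timedelta(days=int(rng.integers(25, 230)))
        e_form = e_date + pd.Timedelta(days=int(rng.integers(0, 20)))
        enr_rows.append({
            "study_id": sid, "cluster_id": cluster, "consent_obtained": consent,
            "enrollment_date": e_date,
            "edd": edd if (consent or rng.random() < 0.7) else None,
            "maternal_height_recorded": rng.random() < 0.9,
            "maternal_weight_recorded": rng.random() < 0.9,
            "anthropometry_timing_recorded": rng.random() < 0.9,
            "enrollment_form_completion_date": e_form,
            "enrollment_data_entry_date": e_form + pd.Timedelta(days=int(rng.integers(0, 60))),
        })
        if not (rng.random() < 0.8):
            continue
        d_date = edd + pd.Timedelta(days=int(rng.integers(-30, 25)))
        is_misc = rng.random() < 0.12
        ga = float(rng.uniform(8, 26)) if is_misc else (
            float(rng.uniform(30, 44)) if rng.random() < 0.9 else None
        )
        d_form = d_date + pd.Timedelta(days=int(rng.integers(0, 45)))
        dlv_rows.append({
            "study_id": sid, "cluster_id": cluster, "delivery_date": d_date,
            "delivery_location": str(rng.choice(["home", "health_center", "hospital", "missing"])),
            "delivery_attendant": str(rng.choice(["physician", "nurse_midwife", "TBA", "missing"])),
            "delivery_mode": str(rng.choice(["vaginal", "cesarean", "missing"])),
            "bag_and_mask_used": "missing" if is_misc else str(rng.choice(["yes", "no", "missing"])),
            "gestational_age_weeks": ga,
            "delivery_form_completion_date": d_form,
            "delivery_data_entry_date": d_form + pd.Timedelta(days=int(rng.integers(0, 60))),
        })
        n_inf = 1 if is_misc else int(rng.integers(1, 3))
        statuses = []
        for j in range(1, n_inf + 1):
            if is_misc:
                status, death = "miscarriage", None
                wt = float(rng.uniform(250, 700))  # some inconsistent (>=500 g)
            else:
                status = str(rng.choice(["live_birth", "stillbirth"], p=[0.88, 0.12]))
                death = None
                if status == "live_birth":
                    u = rng.random()
                    if u < 0.06:
                        death = float(rng.integers(0, 7))
                    elif u < 0.10:
                        death = float(rng.integers(7, 43))
                wt = float(rng.normal(2900, 500)) if rng.random() < 0.85 else None
            has_wt = wt is not None
            bir_rows.append({
                "study_id": sid, "infant_index": j, "status": status,
                "sex": "missing" if is_misc else str(rng.choice(["male", "female", "missing"])),
                "birth_weight_grams": wt,
                "birth_weight_source": str(rng.choice(["measured", "estimated"])) if has_wt else "missing",
                "weight_record_date": d_date + pd.Timedelta(days=int(rng.integers(0, 15))) if has_wt and rng.random() < 0.9 else None,
                "death_day_of_life": death,
            })
            statuses.append(str(rng.choice(["alive", "died", "lost"], p=[0.75, 0.1, 0.15])))
        if rng.random() < 0.85:
            f_form = d_date + pd.Timedelta(days=int(rng.integers(25, 90)))
            fup_rows.append({
                "study_id": sid,
                "followup_form_completion_date": f_form,
                "followup_data_entry_date": f_form + pd.Timedelta(days=int(rng.integers(0, 60))),
                "infant_status_42d": "|".join(statuses),
                "maternal_status_42d": str(rng.choice(["alive", "died", "lost"], p=[0.94, 0.02, 0.04])),
            })
    for k in range(int(rng.integers(0, 20))):
        sid = f"S{int(rng.integers(0, max(n, 1))):04d}" if n else "S0000"
        raised = base + pd.Timedelta(days=int(rng.integers(0, 500)))
        addressed = rng.random() < 0.6
        edit_rows.append({
            "edit_id": f"E{k:03d}", "study_id": sid,
            "form": str(rng.choice(["enrollment", "delivery", "followup"])),
            "field_name": "gestational_age_weeks",
            "check_type": str(rng.choice(["range", "skip", "cross_form", "missing_expected_form"])),
            "severity": str(rng.choice(["critical", "noncritical"])),
            "status": "addressed" if addressed else "open",
            "raised_date": raised,
            "resolved_date": raised + pd.Timedelta(days=int(rng.integers(0, 40))) if addressed else None,
        })
    return make_registry(enr_rows, dlv_rows, bir_rows, fup_rows, edit_rows)


# ---------------------------------------------------------------------------
# shared simulations (expensive; built once per session)
# ---------------------------------------------------------------------------

BASE_CONFIG = SimulationConfig(n_clusters=8, months=24, seed=11)
BASE_AS_OF = "2021-12"


@pytest.fixture(scope="session")
def base_sim() -> RegistryData:
    """Defect-free baseline simulation shared across the suite."""
    return simulate_registry(BASE_CONFIG)
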