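"""Domain model and delimited-file I/O for a maternal-newborn health registry.

A registry extract is five comma-separated UTF-8 tables with header rows:

* ``enrollment.csv`` — one row per consented-or-screened pregnancy
* ``delivery.csv``   — one row per pregnancy with a recorded pregnancy outcome
  (term delivery or miscarriage)
* ``births.csv``     — one row per infant, keyed by (study_id, infant_index)
* ``followup.csv``   — one row per pregnancy with a six-week follow-up form
* ``edits.csv``      — one row per data-quality finding

All dates are ISO-8601 (``YYYY-MM-DD``); booleans are ``true``/``false``;
missing values are empty cells, except in categorical columns that carry an
explicit ``missing`` level (delivery fields, infant sex, birth-weight source),
where missingness is itself data.

Validation is invariant-based: each rule violation yields one
:class:`Diagnostic` naming table, row, field and rule.  In strict mode any
diagnostic aborts the load; in permissive mode offending rows are dropped and
the diagnostics are attached to the returned :class:`RegistryData`.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TABLES",
    "TABLE_COLUMNS",
    "Diagnostic",
    "RegistryData",
    "RegistryValidationError",
    "read_registry_tables",
    "write_registry_tables",
    "validate_registry",
]

TABLES = ("enrollment", "delivery", "births", "followup", "edits")

# column -> kind; kinds: id, str, ostr, bool, date, odate, ofloat, int, oint,
# or a frozenset of allowed categorical levels.
DELIVERY_LOCATIONS = frozenset({"home", "health_center", "hospital", "other", "missing"})
DELIVERY_ATTENDANTS = frozenset({"physician", "nurse_midwife", "TBA", "family", "other", "missing"})
DELIVERY_MODES = frozenset({"vaginal", "cesarean", "missing"})
TRISTATE = frozenset({"yes", "no", "missing"})
BIRTH_STATUSES = frozenset({"live_birth", "stillbirth", "miscarriage"})
SEXES = frozenset({"male", "female", "missing"})
WEIGHT_SOURCES = frozenset({"measured", "estimated", "missing"})
VITAL_STATUSES = frozenset({"alive", "died", "lost"})
EDIT_FORMS = frozenset({"enrollment", "delivery", "followup"})
CHECK_TYPES = frozenset({"range", "skip", "cross_form", "missing_expected_form"})
SEVERITIES = frozenset({"critical", "noncritical"})
EDIT_STATUSES = frozenset({"open", "addressed"})

TABLE_COLUMNS: Mapping[str, Mapping[str, object]] = {
    "enrollment": {
        "study_id": "id",
        "cluster_id": "id",
        "consent_obtained": "bool",
        "enrollment_date": "date",
        "edd": "odate",
        "maternal_height_recorded": "bool",
        "maternal_weight_recorded": "bool",
        "anthropometry_timing_recorded": "bool",
        "enrollment_form_completion_date": "date",
        "enrollment_data_entry_date": "date",
    },
    "delivery": {
        "study_id": "id",
        "cluster_id": "id",
        "delivery_date": "date",
        "delivery_location": DELIVERY_LOCATIONS,
        "delivery_attendant": DELIVERY_ATTENDANTS,
        "delivery_mode": DELIVERY_MODES,
        "bag_and_mask_used": TRISTATE,
        "gestational_age_weeks": "ofloat",
        "delivery_form_completion_date": "date",
        "delivery_data_entry_date": "date",
    },
    "births": {
        "study_id": "id",
        "infant_index": "int",
        "status": BIRTH_STATUSES,
        "sex": SEXES,
        "birth_weight_grams": "ofloat",
        "birth_weight_source": WEIGHT_SOURCES,
        "weight_record_date": "odate",
        "death_day_of_life": "oint",
    },
    "followup": {
        "study_id": "id",
        "followup_form_completion_date": "date",
        "followup_data_entry_date": "date",
        "infant_status_42d": "str",  # pipe-separated per-infant statuses
        "maternal_status_42d": VITAL_STATUSES,
    },
    "edits": {
        "edit_id": "id",
        "study_id": "id",
        "form": EDIT_FORMS,
        "field_name": "str",
        "check_type": CHECK_TYPES,
        "severity": SEVERITIES,
        "status": EDIT_STATUSES,
        "raised_date": "date",
        "resolved_date": "odate",
    },
}

_DATE_KINDS = {"date", "odate"}


@dataclass(frozen=True)
class Diagnostic:
    """One rejected-row finding: which file, row, field, and violated rule."""

    table: str
    row: int  # 1-based data-row number (header excluded)
    study_id: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}.csv row {self.row} [{self.study_id}] {self.field}: {self.rule}"


class RegistryValidationError(ValueError):
    """Raised in strict mode; carries the full list of diagnostics."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        preview = "; ".join(str(d) for d in diagnostics[:5])
        more = "" if len(diagnostics) <= 5 else f" (+{len(diagnostics) - 5} more)"
        super().__init__(f"{len(diagnostics)} invalid rows: {preview}{more}")


@dataclass
class RegistryData:
    """Linked record collections for one registry extract."""

    enrollment: pd.DataFrame
    delivery: pd.DataFrame
    births: pd.DataFrame
    followup: pd.DataFrame
    edits: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLES:
            raise KeyError(name)
        return getattr(self, name)

    def copy(self) -> "RegistryData":
        return RegistryData(
            enrollment=self.enrollment.copy(),
            delivery=self.delivery.copy(),
            births=self.births.copy(),
            followup=self.followup.copy(),
            edits=self.edits.copy(),
            meta=dict(self.meta),
        )

    @property
    def diagnostics(self) -> list[Diagnostic]:
        return list(self.meta.get("diagnostics", []))


def empty_table(name: str) -> pd.DataFrame:
    """An empty, correctly-typed table."""
    cols = TABLE_COLUMNS[name]
    data = {}
    for col, kind in cols.items():
        if kind in _DATE_KINDS:
            data[col] = pd.Series(dtype="datetime64[ns]")
        elif kind == "bool":
            data[col] = pd.Series(dtype=bool)
        elif kind in ("int",):
            data[col] = pd.Series(dtype="int64")
        elif kind in ("oint", "ofloat"):
            data[col] = pd.Series(dtype=float)
        else:
            data[col] = pd.Series(dtype=object)
    return pd.DataFrame(data)


def empty_registry() -> RegistryData:
    return RegistryData(*(empty_table(t) for t in TABLES))


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_table(
    name: str, raw: pd.DataFrame, date_format: str, diags: list[Diagnostic]
) -> pd.DataFrame:
    """Coerce a raw string frame to typed columns, recording parse diagnostics."""
    cols = TABLE_COLUMNS[name]
    unknown = [c for c in raw.columns if c not in cols]
    missing_cols = [c for c in cols if c not in raw.columns]
    if unknown or missing_cols:
        msgs = []
        if unknown:
            msgs.append(f"unknown column(s) {unknown}")
        if missing_cols:
            msgs.append(f"missing column(s) {missing_cols}")
        raise RegistryValidationError(
            [Diagnostic(name, 0, "", "<header>", "; ".join(msgs))]
        )

    out = {}
    bad = pd.Series(False, index=raw.index)
    sid = raw.get("study_id", pd.Series("", index=raw.index)).fillna("").astype(str)

    def flag(mask: pd.Series, col: str, rule: str) -> None:
        nonlocal bad
        for idx in raw.index[mask.fillna(False)]:
            diags.append(Diagnostic(name, int(idx) + 1, sid.loc[idx], col, rule))
        bad |= mask.fillna(False)

    for col, kind in cols.items():
        s = raw[col]
        if isinstance(kind, frozenset):
            v = s.fillna("missing" if "missing" in kind else "").astype(str)
            v = v.replace("", "missing") if "missing" in kind else v
            flag(~v.isin(kind), col, f"value not in {sorted(kind)}")
            out[col] = v
        elif kind in _DATE_KINDS:
            v = pd.to_datetime(s, format=date_format, errors="coerce")
            unparseable = s.notna() & (s.astype(str).str.strip() != "") & v.isna()
            flag(unparseable, col, "unparseable date")
            if kind == "date":
                flag(v.isna() & ~unparseable, col, "required date missing")
            out[col] = v
        elif kind == "bool":
            low = s.fillna("").astype(str).str.strip().str.lower()
            flag(~low.isin(_TRUE | _FALSE), col, "not a boolean")
            out[col] = low.isin(_TRUE)
        elif kind == "id":
            v = s.fillna("").astype(str).str.strip()
            flag(v == "", col, "empty identifier")
            out[col] = v
        elif kind == "str":
            out[col] = s.fillna("").astype(str)
        elif kind in ("ofloat", "oint"):
            v = pd.to_numeric(s, errors="coerce")
            nonempty = s.notna() & (s.astype(str).str.strip() != "")
            flag(nonempty & v.isna(), col, "not a number")
            out[col] = v.astype(float)
        elif kind == "int":
            v = pd.to_numeric(s, errors="coerce")
            flag(v.isna(), col, "required integer missing")
            out[col] = v.fillna(-1).astype("int64")
        else:  # pragma: no cover - schema exhaustive
            raise AssertionError(kind)

    frame = pd.DataFrame(out, index=raw.index)
    frame["_bad"] = bad
    return frame


# ---------------------------------------------------------------------------
# invariant validation
# ---------------------------------------------------------------------------


def validate_registry(data: RegistryData) -> list[Diagnostic]:
    """Check every cross-field and cross-table invariant; return diagnostics.

    Row numbers refer to 0-based positional row index + 1 within each table.
    """
    diags: list[Diagnostic] = []

    def add(table: str, df: pd.DataFrame, mask, field_name: str, rule: str) -> None:
        mask = pd.Series(mask, index=df.index).fillna(False)
        sid = df["study_id"].astype(str) if "study_id" in df else pd.Series("", index=df.index)
        for pos, idx in enumerate(df.index):
            if mask.loc[idx]:
                diags.append(Diagnostic(table, int(df.index.get_loc(idx)) + 1, sid.loc[idx], field_name, rule))

    enr, dlv, bir, fup, edt = (
        data.enrollment,
        data.delivery,
        data.births,
        data.followup,
        data.edits,
    )

    if len(enr):
        dup = enr["study_id"].duplicated(keep=False)
        add("enrollment", enr, dup, "study_id", "duplicate study_id")
        add(
            "enrollment",
            enr,
            enr["enrollment_form_completion_date"] < enr["enrollment_date"],
            "enrollment_form_completion_date",
            "form completed before enrollment",
        )
        add(
            "enrollment",
            enr,
            enr["enrollment_data_entry_date"] < enr["enrollment_form_completion_date"],
            "enrollment_data_entry_date",
            "data entered before form completion",
        )
        add(
            "enrollment",
            enr,
            enr["consent_obtained"] & enr["edd"].isna(),
            "edd",
            "EDD missing for consented record",
        )

    enrolled_ids = set(enr["study_id"]) if len(enr) else set()

    if len(dlv):
        add("delivery", dlv, ~dlv["study_id"].isin(enrolled_ids), "study_id", "no matching enrollment")
        add(
            "delivery",
            dlv,
            dlv["delivery_form_completion_date"] < dlv["delivery_date"],
            "delivery_form_completion_date",
            "form completed before delivery",
        )
        add(
            "delivery",
            dlv,
            dlv["delivery_data_entry_date"] < dlv["delivery_form_completion_date"],
            "delivery_data_entry_date",
            "data entered before form completion",
        )

    if len(bir):
        add("births", bir, ~bir["study_id"].isin(enrolled_ids), "study_id", "no matching enrollment")
        dupb = bir.duplicated(subset=["study_id", "infant_index"], keep=False)
        add("births", bir, dupb, "infant_index", "duplicate (study_id, infant_index)")
        src_missing = bir["birth_weight_source"] == "missing"
        add(
            "births",
            bir,
            src_missing != bir["birth_weight_grams"].isna(),
            "birth_weight_source",
            "birth_weight_source missing iff birth_weight_grams missing violated",
        )
        add(
            "births",
            bir,
            bir["death_day_of_life"].notna() & (bir["status"] != "live_birth"),
            "death_day_of_life",
            "death day recorded for a non-live birth",
        )
        add(
            "births",
            bir,
            bir["death_day_of_life"].notna() & (bir["death_day_of_life"] < 0),
            "death_day_of_life",
            "negative day of life",
        )
        if len(dlv):
            ddate = dlv.set_index("study_id")["delivery_date"]
            mapped = bir["study_id"].map(ddate)
            add(
                "births",
                bir,
                bir["weight_record_date"].notna() & mapped.notna() & (bir["weight_record_date"] < mapped),
                "weight_record_date",
                "weight recorded before delivery",
            )

    if len(fup):
        add("followup", fup, ~fup["study_id"].isin(enrolled_ids), "study_id", "no matching enrollment")
        add("followup", fup, fup["study_id"].duplicated(keep=False), "study_id", "duplicate follow-up record")
        add(
            "followup",
            fup,
            fup["followup_data_entry_date"] < fup["followup_form_completion_date"],
            "followup_data_entry_date",
            "data entered before form completion",
        )
        statuses = fup["infant_status_42d"].astype(str).str.split("|")
        bad_status = statuses.map(lambda xs: any(x not in VITAL_STATUSES for x in xs))
        add("followup", fup, bad_status, "infant_status_42d", "invalid per-infant status")

    if len(edt):
        addressed = edt["status"] == "addressed"
        add(
            "edits",
            edt,
            addressed != edt["resolved_date"].notna(),
            "resolved_date",
            "resolved_date set iff status addressed violated",
        )
        add(
            "edits",
            edt,
            edt["resolved_date"].notna() & (edt["resolved_date"] < edt["raised_date"]),
            "resolved_date",
            "resolved before raised",
        )

    return diags


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------


def _paths_from(source) -> dict[str, str]:
    if isinstance(source, (str, os.PathLike)):
        return {t: os.path.join(os.fspath(source), f"{t}.csv") for t in TABLES}
    return {t: os.fspath(source[t]) for t in TABLES}


def read_registry_tables(
    source,
    *,
    delimiter: str = ",",
    date_format: str = "%Y-%m-%d",
    strict: bool = True,
) -> RegistryData:
    """Read and validate the five registry tables.

    Parameters
    ----------
    source
        Either a directory containing ``enrollment.csv`` … ``edits.csv``, or a
        mapping from table name to file path.
    strict
        If True (default), any diagnostic raises
        :class:`RegistryValidationError`.  If False, rows with violations are
        dropped and the diagnostics are kept in ``data.meta['diagnostics']``.
    """
    paths = _paths_from(source)
    for t, p in paths.items():
        if not os.path.exists(p):
            raise FileNotFoundError(f"missing registry table {t}: {p}")

    diags: list[Diagnostic] = []
    typed: dict[str, pd.DataFrame] = {}
    for t, p in paths.items():
        raw = pd.read_csv(p, sep=delimiter, dtype=str, keep_default_na=True)
        raw.index = pd.RangeIndex(len(raw))
        typed[t] = _parse_table(t, raw, date_format, diags)

    # drop structurally-unparseable rows before invariant checks
    frames = {}
    for t, df in typed.items():
        frames[t] = df.loc[~df["_bad"]].drop(columns="_bad").reset_index(drop=True)

    data = RegistryData(**frames)
    diags.extend(validate_registry(data))

    if diags:
        if strict:
            raise RegistryValidationError(diags)
        # permissive: drop every row named by a diagnostic
        bad_rows: dict[str, set[int]] = {t: set() for t in TABLES}
        for d in diags:
            if d.row >= 1:
                bad_rows[d.table].add(d.row - 1)
        for t in TABLES:
            df = data.table(t)
            keep = [i for i in range(len(df)) if i not in bad_rows[t]]
            setattr(data, t, df.iloc[keep].reset_index(drop=True))
        data.meta["diagnostics"] = diags
    return data


def _format_table(name: str, df: pd.DataFrame, date_format: str) -> pd.DataFrame:
    cols = TABLE_COLUMNS[name]
    out = pd.DataFrame(index=df.index)
    for col, kind in cols.items():
        s = df[col]
        if kind in _DATE_KINDS:
            out[col] = pd.to_datetime(s).dt.strftime(date_format)
        elif kind == "bool":
            out[col] = np.where(s.astype(bool), "true", "false")
        elif kind == "oint":
            out[col] = s.map(lambda x: "" if pd.isna(x) else str(int(x)))
        elif kind == "int":
            out[col] = s.astype("int64").astype(str)
        elif kind == "ofloat":
            out[col] = s.map(lambda x: "" if pd.isna(x) else format(float(x), "g"))
        else:
            out[col] = s.fillna("").astype(str)
    return out.fillna("")


def write_registry_tables(
    data: RegistryData,
    outdir,
    *,
    delimiter: str = ",",
    date_format: str = "%Y-%m-%d",
) -> dict[str, str]:
    """Write the five tables as delimited text; returns table→path."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for t in TABLES:
        p = os.path.join(outdir, f"{t}.csv")
        _format_table(t, data.table(t), date_format).to_csv(p, sep=delimiter, index=False)
        paths[t] = p
    return paths
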