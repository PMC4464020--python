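"""The shipped data-quality indicator catalogue.

Each indicator carries its acceptable value as printed in the registry's
monitoring protocol: a single lower or upper bound, a closed range, or an
exact per-month minimum.  Flagging is inclusive at the bound (a value exactly
at the threshold is acceptable); see :func:`registryqc.metrics.evaluate_flag`.

Two indicators need a word on their encoding:

* ``miscarriage_consistency`` — the protocol states a per-record rule
  (gestational age < 20 weeks and weight < 500 g for miscarriages) rather
  than a percentage.  It is shipped as "proportion of assessable miscarriages
  consistent with the rule" with lower bound 100: any violation is a data
  error (and also raises a critical edit).
* ``weight_record_latency`` — the protocol gives the bound in days (< 7 days
  from birth to a recorded weight) with no percentage; the metric value is
  the median latency in days, flagged at_most 7.  The companion
  ``bw_within_7d`` indicator carries the percentage form (> 95%).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import yaml

__all__ = ["MetricDefinition", "DEFAULT_CATALOGUE", "load_metric_catalogue"]

CATEGORIES = ("enrollment", "pregnancy_outcome", "mortality", "key_variable", "process")
BOUND_SEMANTICS = ("at_least", "at_most", "within_range", "exact_minimum")
UNITS = ("proportion_pct", "ratio", "count", "days")


@dataclass(frozen=True)
class MetricDefinition:
    metric_id: str
    category: str
    description: str
    lower_bound: float | None
    upper_bound: float | None
    bound_semantics: str
    units: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.bound_semantics not in BOUND_SEMANTICS:
            raise ValueError(f"unknown bound_semantics {self.bound_semantics!r}")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        if self.bound_semantics == "within_range":
            if self.lower_bound is None or self.upper_bound is None:
                raise ValueError(f"{self.metric_id}: within_range needs both bounds")
            if self.lower_bound > self.upper_bound:
                raise ValueError(f"{self.metric_id}: lower_bound > upper_bound")
        if self.bound_semantics in ("at_least", "exact_minimum") and self.lower_bound is None:
            raise ValueError(f"{self.metric_id}: {self.bound_semantics} needs lower_bound")
        if self.bound_semantics == "at_most" and self.upper_bound is None:
            raise ValueError(f"{self.metric_id}: at_most needs upper_bound")


def _d(mid, cat, desc, lo, hi, sem, units) -> MetricDefinition:
    return MetricDefinition(mid, cat, desc, lo, hi, sem, units)


# One definition per indicator row of the monitoring protocol, in protocol order.
_DEFS: tuple[MetricDefinition, ...] = (
    # --- enrollment ---
    _d("consent_rate", "enrollment",
       "Proportion of enrolled subjects with consent obtained",
       95.0, None, "at_least", "proportion_pct"),
    _d("enroll_variability", "enrollment",
       "Month-to-month enrollment variability factor over the past 6 months "
       "(highest monthly enrollment / lowest monthly enrollment)",
       None, 2.0, "at_most", "ratio"),
    # --- pregnancy outcome ---
    _d("delivery_outcome", "pregnancy_outcome",
       "Proportion of expected delivery outcomes obtained",
       95.0, None, "at_least", "proportion_pct"),
    _d("followup_outcome", "pregnancy_outcome",
       "Proportion of deliveries with a 6-week neonatal outcome obtained",
       95.0, None, "at_least", "proportion_pct"),
    _d("sex_ratio", "pregnancy_outcome",
       "Male:female ratio among registered births with known sex",
       0.80, 1.30, "within_range", "ratio"),
    _d("birth_variability", "pregnancy_outcome",
       "Month-to-month birth variability factor over the past 6 months "
       "(highest monthly births / lowest monthly births)",
       None, 2.0, "at_most", "ratio"),
    _d("expected_deliveries", "pregnancy_outcome",
       "Ratio of expected deliveries (EDD pipeline over the next 6 months) "
       "to average monthly deliveries",
       70.0, None, "at_least", "proportion_pct"),
    _d("min_deliveries", "pregnancy_outcome",
       "Minimum number of deliveries per month per cluster",
       25.0, None, "exact_minimum", "count"),
    # --- mortality ---
    _d("sb_end_ratio", "mortality",
       "Ratio of stillbirths to early neonatal deaths",
       0.50, 2.0, "within_range", "ratio"),
    _d("end_sixweek_ratio", "mortality",
       "Ratio of early neonatal deaths to 6-week neonatal deaths",
       0.60, 0.90, "within_range", "ratio"),
    _d("miscarriage_consistency", "mortality",
       "Proportion of assessable miscarriages with gestational age < 20 weeks "
       "and birth weight < 500 g",
       100.0, None, "at_least", "proportion_pct"),
    # --- key variables ---
    _d("bw_measured_live", "key_variable",
       "Proportion of live births with a measured birth weight",
       95.0, None, "at_least", "proportion_pct"),
    _d("bw_measured_neodeath", "key_variable",
       "Proportion of neonatal deaths (death by day 42) with a measured birth weight",
       90.0, None, "at_least", "proportion_pct"),
    _d("bw_measured_stillbirth", "key_variable",
       "Proportion of stillbirths with a measured birth weight",
       75.0, None, "at_least", "proportion_pct"),
    _d("bw_any_live", "key_variable",
       "Proportion of live births with any birth weight recorded",
       99.0, None, "at_least", "proportion_pct"),
    _d("bw_any_neodeath", "key_variable",
       "Proportion of neonatal deaths with any birth weight recorded",
       95.0, None, "at_least", "proportion_pct"),
    _d("bw_any_stillbirth", "key_variable",
       "Proportion of stillbirths with any birth weight recorded",
       95.0, None, "at_least", "proportion_pct"),
    _d("anthro_complete", "key_variable",
       "Proportion of enrolled subjects with maternal height, weight and "
       "anthropometry timing recorded",
       95.0, None, "at_least", "proportion_pct"),
    _d("delivery_fields_complete", "key_variable",
       "Proportion of deliveries with delivery attendant, location, mode, "
       "bag-and-mask use and gestational age recorded",
       99.0, None, "at_least", "proportion_pct"),
    _d("bw_within_7d", "key_variable",
       "Proportion of deliveries with birth weight collected within 7 days of birth",
       95.0, None, "at_least", "proportion_pct"),
    # --- process ---
    _d("weight_record_latency", "process",
       "Days between birth and a measured (or estimated) birth weight recorded "
       "(median; per-record rule < 7 days)",
       None, 7.0, "at_most", "days"),
    _d("enroll_entry_6w", "process",
       "Proportion with time between enrollment and data entry < 6 weeks",
       90.0, None, "at_least", "proportion_pct"),
    _d("enroll_edd_4w", "process",
       "Proportion with time between enrollment and EDD > 4 weeks",
       70.0, None, "at_least", "proportion_pct"),
    _d("delivery_info_entry_6w", "process",
       "Proportion with time between collection of delivery information and "
       "data entry < 6 weeks",
       90.0, None, "at_least", "proportion_pct"),
    _d("delivery_form_4w", "process",
       "Proportion with time between delivery and completion of delivery form < 4 weeks",
       90.0, None, "at_least", "proportion_pct"),
    _d("form_entry_6w", "process",
       "Proportion with time between completion of delivery form and data entry < 6 weeks",
       90.0, None, "at_least", "proportion_pct"),
    _d("followup_form_5_9w", "process",
       "Proportion with time between delivery and completion of follow-up form "
       "between 5 and 9 weeks",
       80.0, None, "at_least", "proportion_pct"),
    _d("followup_entry_6w", "process",
       "Proportion with time between completion of follow-up form and data entry < 6 weeks",
       90.0, None, "at_least", "proportion_pct"),
    _d("critical_edits", "process",
       "Proportion of critical edits addressed",
       80.0, None, "at_least", "proportion_pct"),
)

DEFAULT_CATALOGUE: dict[str, MetricDefinition] = {d.metric_id: d for d in _DEFS}


def load_metric_catalogue(config_path: str | os.PathLike | None = None) -> dict[str, MetricDefinition]:
    """Return the indicator catalogue, optionally overriding bounds.

    The override file is a flat YAML mapping ``metric_id -> {lower_bound,
    upper_bound}``; metric identities (ids, categories, semantics, units)
    cannot be changed and unknown ids are rejected.
    """
    catalogue = dict(DEFAULT_CATALOGUE)
    if config_path is None:
        return catalogue
    with open(config_path, "r", encoding="utf-8") as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise ValueError("catalogue override file must be a mapping of metric_id to bounds")
    for mid, spec in overrides.items():
        if mid not in catalogue:
            raise KeyError(f"override references unknown metric_id {mid!r}")
        if not isinstance(spec, dict) or not set(spec) <= {"lower_bound", "upper_bound"}:
            raise ValueError(f"override for {mid!r} may only set lower_bound/upper_bound")
        kwargs = {k: (None if v is None else float(v)) for k, v in spec.items()}
        catalogue[mid] = replace(catalogue[mid], **kwargs)
    return catalogue
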