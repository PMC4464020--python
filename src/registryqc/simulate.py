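"""Seeded synthetic registry simulator.

Emulates a multi-cluster, population-based pregnancy registry: each cluster
is a catchment of roughly 300-500 births per year, pregnancies are enrolled
well before the estimated date of delivery, outcomes (miscarriage,
stillbirth, live birth, early/late neonatal death, maternal death) are drawn
per configured probabilities, and every form carries realistic
completion/data-entry latencies.

The monthly birth process is an inhomogeneous Poisson process with sinusoidal
seasonality.  Default latency distributions are log-normal with medians well
inside the protocol's process windows, and default recording probabilities
are high, so a defect-free simulation is a known-good baseline: it passes
every indicator and raises no edit items.  Data-quality problems are added
separately and orthogonally by :mod:`registryqc.defects`.

Default mortality rates are placeholders in plausible ranges for
high-mortality settings, not estimates for any particular site.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import RegistryData, empty_table

__all__ = ["SimulationConfig", "LatencyConfig", "simulate_registry"]


@dataclass(frozen=True)
class LatencyConfig:
    """Log-normal day-count latency: exp(Normal(log(median), sigma))."""

    median_days: float
    sigma: float = 0.5
    max_days: float | None = None  # optional hard cap

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        days = np.exp(rng.normal(np.log(self.median_days), self.sigma, size=n))
        if self.max_days is not None:
            days = np.minimum(days, self.max_days)
        return np.round(days).astype(int)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic registry.

    ``births_per_cluster_year`` is a (low, high) range; each cluster's annual
    volume is drawn uniformly from it.  ``enrollment_lead_*`` parameterise the
    normal distribution of days between enrollment and the EDD (clipped to
    [42, 238] days, i.e. enrollment roughly by 20 weeks gestation).
    """

    n_clusters: int = 10
    births_per_cluster_year: tuple[float, float] = (300.0, 500.0)
    months: int = 24
    start_month: str = "2020-01"
    seasonality_amplitude: float = 0.15

    p_stillbirth: float = 0.030
    p_early_neonatal_death: float = 0.025  # death on day of life 0-6
    p_late_neonatal_death: float = 0.008  # death on day of life 7-42
    p_miscarriage: float = 0.020
    p_maternal_death: float = 0.002
    p_male: float = 0.515
    p_twin: float = 0.012
    p_consent: float = 0.998
    p_lost_followup: float = 0.005
    p_sex_missing: float = 0.002
    p_anthro_recorded: float = 0.998  # each of the three anthropometry flags

    # birth-weight source probabilities (measured, estimated, missing)
    bw_source_live: tuple[float, float, float] = (0.990, 0.009, 0.001)
    bw_source_stillbirth: tuple[float, float, float] = (0.970, 0.025, 0.005)

    enrollment_lead_mean: float = 170.0
    enrollment_lead_sd: float = 25.0

    latency_enrollment_form: LatencyConfig = LatencyConfig(1.0, 0.5)
    latency_form_entry: LatencyConfig = LatencyConfig(7.0, 0.5)
    latency_delivery_form: LatencyConfig = LatencyConfig(5.0, 0.5)
    latency_weight_record: LatencyConfig = LatencyConfig(1.0, 0.6)
    # offset past the 42-day visit; capped so follow-up stays within 9 weeks
    latency_followup_form: LatencyConfig = LatencyConfig(5.0, 0.5, max_days=20.0)

    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_stillbirth": self.p_stillbirth,
            "p_early_neonatal_death": self.p_early_neonatal_death,
            "p_late_neonatal_death": self.p_late_neonatal_death,
            "p_miscarriage": self.p_miscarriage,
            "p_maternal_death": self.p_maternal_death,
            "p_male": self.p_male,
            "p_twin": self.p_twin,
            "p_consent": self.p_consent,
            "p_lost_followup": self.p_lost_followup,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_stillbirth + self.p_miscarriage > 1.0:
            raise ValueError("p_stillbirth + p_miscarriage must not exceed 1")
        if self.p_early_neonatal_death + self.p_late_neonatal_death > 1.0:
            raise ValueError("neonatal death probabilities must not exceed 1 combined")
        if self.months < 1:
            raise ValueError("months must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        lo, hi = self.births_per_cluster_year
        if not (0 < lo <= hi):
            raise ValueError("births_per_cluster_year range must be non-empty and positive")
        if not 0.0 <= self.seasonality_amplitude < 1.0:
            raise ValueError("seasonality_amplitude must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in (
            "latency_enrollment_form", "latency_form_entry", "latency_delivery_form",
            "latency_weight_record", "latency_followup_form",
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = LatencyConfig(**raw[key])
        for key in ("births_per_cluster_year", "bw_source_live", "bw_source_stillbirth"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# gestation constants (days)
_TERM_EDD_SD = 5.0  # EDD error around the true delivery date
_PIPELINE_EXTRA_MONTHS = 8  # future pregnancies emitted as enrollment-only rows


def _pick(rng: np.random.Generator, values: list[str], probs: list[float]) -> str:
    return values[int(rng.choice(len(values), p=np.asarray(probs) / np.sum(probs)))]


def simulate_registry(config: SimulationConfig) -> RegistryData:
    """Simulate a registry extract; deterministic given ``config.seed``.

    Pregnancies ending after the simulated span appear as enrollment-only
    rows when their enrollment date falls inside the span — they form the
    expected-deliveries pipeline.  The output satisfies every registry
    invariant, and ``data.meta`` records the seed and span.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Period(config.start_month, freq="M")
    span_end_date = (start + (config.months - 1)).to_timestamp(how="end").normalize()

    enr_rows, dlv_rows, bir_rows, fup_rows = [], [], [], []
    phase = rng.uniform(0.0, 12.0)  # site-wide seasonal phase

    for c in range(config.n_clusters):
        cluster_id = f"C{c + 1:02d}"
        annual = rng.uniform(*config.births_per_cluster_year)
        base_monthly = annual / 12.0
        counter = 0
        for m in range(config.months + _PIPELINE_EXTRA_MONTHS):
            rate = base_monthly * (
                1.0 + config.seasonality_amplitude * np.sin(2 * np.pi * (m + phase) / 12.0)
            )
            n = rng.poisson(rate)
            month = start + m
            month_start = month.to_timestamp(how="start")
            days_in_month = month.days_in_month
            in_span = m < config.months
            for _ in range(n):
                counter += 1
                study_id = f"{cluster_id}-{counter:05d}"
                end_date = month_start + pd.Timedelta(days=int(rng.integers(0, days_in_month)))

                is_misc = rng.random() < config.p_miscarriage
                if is_misc:
                    ga = float(np.round(rng.uniform(8.0, 19.5), 1))
                    edd = end_date + pd.Timedelta(days=int(round((40.0 - ga) * 7)))
                    enrollment_date = end_date - pd.Timedelta(days=int(rng.integers(7, 46)))
                else:
                    ga = float(np.round(np.clip(rng.normal(39.0, 1.5), 31.0, 44.0), 1))
                    edd = end_date + pd.Timedelta(days=int(round(rng.normal(0.0, _TERM_EDD_SD))))
                    lead = int(np.clip(rng.normal(config.enrollment_lead_mean, config.enrollment_lead_sd), 42, 238))
                    enrollment_date = edd - pd.Timedelta(days=lead)

                if enrollment_date > span_end_date:
                    continue  # not yet known to the registry

                consent = rng.random() < config.p_consent
                e_form = enrollment_date + pd.Timedelta(
                    days=int(config.latency_enrollment_form.draw(rng, 1)[0])
                )
                e_entry = e_form + pd.Timedelta(days=int(config.latency_form_entry.draw(rng, 1)[0]))
                enr_rows.append({
                    "study_id": study_id,
                    "cluster_id": cluster_id,
                    "consent_obtained": consent,
                    "enrollment_date": enrollment_date,
                    "edd": edd,
                    "maternal_height_recorded": rng.random() < config.p_anthro_recorded,
                    "maternal_weight_recorded": rng.random() < config.p_anthro_recorded,
                    "anthropometry_timing_recorded": rng.random() < config.p_anthro_recorded,
                    "enrollment_form_completion_date": e_form,
                    "enrollment_data_entry_date": e_entry,
                })

                if not consent or not in_span:
                    continue  # no outcome forms: unconsented, or pregnancy still ongoing

                # ---- pregnancy outcome forms ----
                d_form = end_date + pd.Timedelta(days=int(config.latency_delivery_form.draw(rng, 1)[0]))
                d_entry = d_form + pd.Timedelta(days=int(config.latency_form_entry.draw(rng, 1)[0]))

                if is_misc:
                    dlv_rows.append({
                        "study_id": study_id,
                        "cluster_id": cluster_id,
                        "delivery_date": end_date,
                        "delivery_location": _pick(rng, ["home", "health_center", "hospital", "other"], [0.35, 0.40, 0.23, 0.02]),
                        "delivery_attendant": _pick(rng, ["physician", "nurse_midwife", "TBA", "family", "other"], [0.18, 0.50, 0.22, 0.08, 0.02]),
                        "delivery_mode": "vaginal",
                        "bag_and_mask_used": "missing",  # skip field for miscarriages
                        "gestational_age_weeks": ga,
                        "delivery_form_completion_date": d_form,
                        "delivery_data_entry_date": d_entry,
                    })
                    wt = float(np.round(rng.uniform(210.0, 490.0)))
                    bir_rows.append({
                        "study_id": study_id,
                        "infant_index": 1,
                        "status": "miscarriage",
                        "sex": "missing",
                        "birth_weight_grams": wt,
                        "birth_weight_source": "estimated",
                        "weight_record_date": end_date + pd.Timedelta(days=int(config.latency_weight_record.draw(rng, 1)[0])),
                        "death_day_of_life": np.nan,
                    })
                    statuses = ["died"]
                else:
                    n_infants = 2 if rng.random() < config.p_twin else 1
                    statuses = []
                    any_resusc = False
                    for i in range(1, n_infants + 1):
                        if rng.random() < config.p_stillbirth:
                            status, death_day = "stillbirth", np.nan
                            src_probs = config.bw_source_stillbirth
                            statuses.append("died")
                        else:
                            status = "live_birth"
                            u = rng.random()
                            if u < config.p_early_neonatal_death:
                                death_day = float(rng.integers(0, 7))
                                any_resusc = True
                            elif u < config.p_early_neonatal_death + config.p_late_neonatal_death:
                                death_day = float(rng.integers(7, 43))
                            else:
                                death_day = np.nan
                            src_probs = config.bw_source_live
                            if not np.isnan(death_day):
                                statuses.append("died")
                            elif rng.random() < config.p_lost_followup:
                                statuses.append("lost")
                            else:
                                statuses.append("alive")
                        sex = "missing" if rng.random() < config.p_sex_missing else (
                            "male" if rng.random() < config.p_male else "female"
                        )
                        source = _pick(rng, ["measured", "estimated", "missing"], list(src_probs))
                        if source == "missing":
                            wt, wdate = np.nan, pd.NaT
                        else:
                            mean_wt = 2950.0 if status == "live_birth" else 2500.0
                            wt = float(np.round(np.clip(rng.normal(mean_wt, 450.0), 800.0, 5200.0)))
                            wdate = end_date + pd.Timedelta(days=int(config.latency_weight_record.draw(rng, 1)[0]))
                        bir_rows.append({
                            "study_id": study_id,
                            "infant_index": i,
                            "status": status,
                            "sex": sex,
                            "birth_weight_grams": wt,
                            "birth_weight_source": source,
                            "weight_record_date": wdate,
                            "death_day_of_life": death_day,
                        })
                    dlv_rows.append({
                        "study_id": study_id,
                        "cluster_id": cluster_id,
                        "delivery_date": end_date,
                        "delivery_location": _pick(rng, ["home", "health_center", "hospital", "other"], [0.30, 0.40, 0.28, 0.02]),
                        "delivery_attendant": _pick(rng, ["physician", "nurse_midwife", "TBA", "family", "other"], [0.20, 0.50, 0.20, 0.08, 0.02]),
                        "delivery_mode": "cesarean" if rng.random() < 0.10 else "vaginal",
                        "bag_and_mask_used": "yes" if (any_resusc or rng.random() < 0.04) else "no",
                        "gestational_age_weeks": ga,
                        "delivery_form_completion_date": d_form,
                        "delivery_data_entry_date": d_entry,
                    })

                f_form = end_date + pd.Timedelta(
                    days=42 + int(config.latency_followup_form.draw(rng, 1)[0])
                )
                f_entry = f_form + pd.Timedelta(days=int(config.latency_form_entry.draw(rng, 1)[0]))
                fup_rows.append({
                    "study_id": study_id,
                    "followup_form_completion_date": f_form,
                    "followup_data_entry_date": f_entry,
                    "infant_status_42d": "|".join(statuses),
                    "maternal_status_42d": "died" if rng.random() < config.p_maternal_death else "alive",
                })

    def frame(name: str, rows: list[dict]) -> pd.DataFrame:
        if not rows:
            return empty_table(name)
        df = pd.DataFrame(rows)
        for col in df.columns:
            if col.endswith("date") or col == "edd":
                df[col] = pd.to_datetime(df[col])
        return df

    data = RegistryData(
        enrollment=frame("enrollment", enr_rows),
        delivery=frame("delivery", dlv_rows),
        births=frame("births", bir_rows),
        followup=frame("followup", fup_rows),
        edits=empty_table("edits"),
    )
    data.meta.update({
        "seed": config.seed,
        "start_month": str(start),
        "end_month": str(start + (config.months - 1)),
        "n_clusters": config.n_clusters,
    })
    return data
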