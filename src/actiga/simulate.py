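"""Synthetic actigraphy cohorts with a planted gestational-age clock.

Generates week-plus recordings of minute-epoch (activity, light) counts with
a smoothed diurnal base profile (wake 07:00-23:00), a GA-dependent drift of
daily rest minutes, multiplicative lognormal count noise, and — for the
planted rhythm-disrupted PTB+ subgroup — extra daytime rest bouts, nocturnal
activity bouts and phase jitter that lower interdaily stability and bias the
apparent rest duration upward. A correlated metadata table covers the six
variable categories (sleep, activity, stress, comorbidity, social, outcome).

The generator exists so every downstream module is testable without the
original cohort; it makes no claim of physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .circadian import MINUTES_PER_DAY, interdaily_stability, oakley_sleep_wake
from .io import ActigraphyRecording, MetadataTable

_WAKE_ON = 7 * 60  # 07:00
_WAKE_OFF = 23 * 60  # 23:00
_NIGHT_LEVEL = 2.0  # residual nocturnal counts
_GA_REF_WEEKS = 22.5  # centre of the GA range; rest drift is relative to it


@dataclass
class SimulationConfig:
    """Cohort-level generative settings.

    Defaults emulate the study conditions: ~1083 pregnant individuals wearing
    the device for 9 days at 1-min epochs, GA spanning 5-40 weeks, a ~14%
    preterm (PTB+) subgroup whose rhythm is disrupted.
    """

    n_patients: int = 1083
    measurements_per_patient: int = 2
    epoch_minutes: int = 1
    days: int = 9
    seed: int = 0
    ga_range_weeks: tuple = (5.0, 40.0)
    ptb_fraction: float = 0.141
    diurnal_amplitude: float = 150.0
    noise_sd: float = 0.35
    ga_rest_slope: float = 15.0  # weekly rest minutes gained per GA week
    disruption_strength: float = 0.6
    phase_jitter_sd: float = 10.0  # minutes, per day, for undisrupted patients
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 1 <= self.measurements_per_patient <= 3:
            raise ConfigError("measurements_per_patient must be in 1..3")
        if self.epoch_minutes != 1:
            raise ConfigError("epoch_minutes must equal 1")
        if self.days < 8:
            raise ConfigError("days must be >= 8 (first-day drop must leave a full week)")
        if not 0.0 <= self.ptb_fraction <= 1.0:
            raise ConfigError("ptb_fraction must lie in [0, 1]")
        if not 0.0 <= self.disruption_strength <= 1.0:
            raise ConfigError("disruption_strength must lie in [0, 1]")
        lo, hi = self.ga_range_weeks
        if not (lo < hi and lo >= 0):
            raise ConfigError("ga_range_weeks must be an increasing nonnegative interval")
        if self.noise_sd < 0 or self.diurnal_amplitude <= 0:
            raise ConfigError("noise_sd must be >= 0 and diurnal_amplitude > 0")


@dataclass
class SyntheticTruth:
    """Ground truth: one record per patient and one per measurement."""

    patients: pd.DataFrame  # patient_id, ptb, disruption, is_target
    measurements: pd.DataFrame  # sample_id, patient_id, ga_weeks


def _smooth_circular(profile: np.ndarray, kernel_minutes: int = 60) -> np.ndarray:
    kernel = np.ones(kernel_minutes) / kernel_minutes
    padded = np.concatenate([profile[-kernel_minutes:], profile, profile[:kernel_minutes]])
    return np.convolve(padded, kernel, mode="same")[kernel_minutes:-kernel_minutes]


def _day_profile(
    amplitude: float,
    rest_delta_daily: float,
    phase_shift: float,
) -> np.ndarray:
    """Smoothed rectangular day: wake window shrinks by `rest_delta_daily` minutes."""
    on = _WAKE_ON + rest_delta_daily / 2 + phase_shift
    off = _WAKE_OFF - rest_delta_daily / 2 + phase_shift
    t = np.arange(MINUTES_PER_DAY)
    base = np.where((t >= on) & (t < off), amplitude, _NIGHT_LEVEL)
    return _smooth_circular(base)


def _simulate_measurement(cfg: SimulationConfig, ga: float, disruption: float, rng) -> np.ndarray:
    """Per-minute expected activity over `cfg.days` days, before count noise."""
    rest_delta = cfg.ga_rest_slope * (ga - _GA_REF_WEEKS) / 7.0  # daily minutes
    phase_sd = cfg.phase_jitter_sd * (1.0 + 6.0 * disruption)
    days = []
    for _ in range(cfg.days):
        profile = _day_profile(cfg.diurnal_amplitude, rest_delta, rng.normal(0, phase_sd))
        if disruption > 0:
            # daytime fatigue naps: planted apparent-rest excess for PTB+
            for _ in range(rng.poisson(3.0 * disruption)):
                start = rng.integers(_WAKE_ON, _WAKE_OFF - 60)
                dur = int(rng.integers(20, 70))
                profile[start : start + dur] = _NIGHT_LEVEL
            # nocturnal activity bouts: fragmentation
            for _ in range(rng.poisson(4.0 * disruption)):
                start = int(rng.integers(0, _WAKE_ON - 30)) if rng.random() < 0.5 else int(
                    rng.integers(_WAKE_OFF, MINUTES_PER_DAY - 30)
                )
                dur = int(rng.integers(5, 25))
                profile[start : start + dur] += rng.uniform(0.3, 0.8) * cfg.diurnal_amplitude
        days.append(profile)
    return np.concatenate(days)


def generate_cohort(config: SimulationConfig):
    """Generate (recordings, metadata, truth) for one synthetic cohort.

    Deterministic for a fixed config (identical seed => bit-identical cohort).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ga_range_weeks
    start = pd.Timestamp("2019-01-01 00:00")

    recordings, meta_rows, patient_rows, meas_rows = [], [], [], []
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        ptb = bool(rng.random() < config.ptb_fraction)
        disruption = config.disruption_strength if ptb else 0.0
        patient_rows.append(
            {
                "patient_id": pid,
                "ptb": ptb,
                "disruption": disruption,
                "is_target": 1.0 / (1.0 + 2.0 * disruption),
            }
        )
        frag_score = disruption + rng.normal(0, 0.05)
        for m in range(config.measurements_per_patient):
            ga = float(rng.uniform(lo, hi))
            mean_profile = _simulate_measurement(config, ga, disruption, rng)
            noise = rng.lognormal(mean=0.0, sigma=config.noise_sd, size=mean_profile.size)
            activity = np.round(mean_profile * noise).astype(int)
            activity = np.maximum(activity, 0)
            light = np.maximum(
                np.round(0.5 * activity + rng.normal(0, 5.0, activity.size)), 0
            ).astype(int)
            gap = False
            if config.missing_rate > 0:
                drop = rng.random(activity.size) < config.missing_rate
                gap = bool(drop.any())
                activity = activity[~drop]
                light = light[~drop]
            sample_id = f"{pid}m{m}"
            recordings.append(
                ActigraphyRecording(
                    patient_id=pid,
                    start_time=start,
                    activity=activity,
                    light=light,
                    has_gap=gap,
                )
            )
            meas_rows.append({"sample_id": sample_id, "patient_id": pid, "ga_weeks": ga})
            meta_rows.append(
                _metadata_row(sample_id, pid, ga, ptb, frag_score, rng)
            )

    metadata = MetadataTable(pd.DataFrame(meta_rows), kinds=_META_KINDS, categories=_META_CATEGORIES)
    truth = SyntheticTruth(pd.DataFrame(patient_rows), pd.DataFrame(meas_rows))
    return recordings, metadata, truth


_META_KINDS = {
    "psqi": "ordinal",
    "sleep_quality_good": "categorical",
    "kpas": "continuous",
    "stress_score": "continuous",
    "depression": "categorical",
    "hypertension": "categorical",
    "diabetes": "categorical",
    "education_level": "categorical",
    "employment": "categorical",
    "ptb": "categorical",
    "corticosteroids": "categorical",
}

_META_CATEGORIES = {
    "psqi": "sleep",
    "sleep_quality_good": "sleep",
    "kpas": "activity",
    "stress_score": "stress",
    "depression": "stress",
    "hypertension": "comorbidity",
    "diabetes": "comorbidity",
    "education_level": "social",
    "employment": "social",
    "ptb": "outcome",
    "corticosteroids": "outcome",
}


def _metadata_row(sample_id, pid, ga, ptb, frag, rng) -> dict:
    """Mixed metadata with planted correlations to the fragmentation level."""
    psqi = int(np.clip(round(8 + 6 * frag + rng.normal(0, 1.5)), 0, 21))
    return {
        "sample_id": sample_id,
        "patient_id": pid,
        "psqi": psqi,
        "sleep_quality_good": "yes" if psqi <= 5 else "no",
        "kpas": float(np.clip(9.5 - 2.0 * frag + rng.normal(0, 1.0), 0, 20)),
        "stress_score": float(np.clip(5 + 4 * frag + rng.normal(0, 1.5), 0, 20)),
        "depression": bool(rng.random() < 0.10 + 0.25 * frag),
        "hypertension": bool(rng.random() < 0.08 + 0.30 * frag),
        "diabetes": bool(rng.random() < 0.04 + 0.15 * frag),
        "education_level": str(rng.choice(["primary", "secondary", "tertiary"])),
        "employment": str(rng.choice(["employed", "unemployed", "student"])),
        "ptb": bool(ptb),
        "corticosteroids": bool(rng.random() < (0.6 if ptb else 0.03)),
    }


def planted_effect_report(recordings, truth: SyntheticTruth, oakley_threshold: float = 80.0) -> dict:
    """Summarise the realised GA-rest correlation and the PTB+/- IS gap.

    Rest minutes come from Oakley scoring of each recording's first full week;
    IS from the raw counts. Refuses cohorts with fewer than 3 patients.
    """
    if truth.patients.shape[0] < 3:
        raise ValueError("planted_effect_report needs at least 3 patients")
    if len(recordings) != truth.measurements.shape[0]:
        raise ValueError("recordings and truth measurements are misaligned")
    ptb_by_patient = dict(zip(truth.patients.patient_id, truth.patients.ptb))

    rest, ga, is_vals, ptb_flags = [], [], [], []
    for rec, meas in zip(recordings, truth.measurements.itertuples()):
        week = rec.activity[: 7 * MINUTES_PER_DAY]
        if week.size < 7 * MINUTES_PER_DAY:
            continue
        mask = oakley_sleep_wake(week, threshold=oakley_threshold)
        rest.append(float(mask.sum()))
        ga.append(float(meas.ga_weeks))
        ptb_flags.append(bool(ptb_by_patient[meas.patient_id]))
        is_vals.append(interdaily_stability(week))

    rest, ga, is_vals = np.array(rest), np.array(ga), np.array(is_vals)
    ptb_flags = np.array(ptb_flags)
    rho, rho_p = stats.spearmanr(ga, rest)
    # Fisher-z 95% CI for the rank correlation
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(max(len(ga) - 3, 1))
    ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))

    is_pos = is_vals[ptb_flags]
    is_neg = is_vals[~ptb_flags]
    gap = float(is_neg.mean() - is_pos.mean()) if is_pos.size and is_neg.size else float("nan")
    if is_pos.size and is_neg.size:
        gap_se = float(np.sqrt(is_pos.var(ddof=1) / is_pos.size + is_neg.var(ddof=1) / is_neg.size))
    else:
        gap_se = float("nan")
    return {
        "ga_rest_spearman": float(rho),
        "ga_rest_p": float(rho_p),
        "ga_rest_ci": ci,
        "is_gap": gap,
        "is_gap_ci": (gap - 1.96 * gap_se, gap + 1.96 * gap_se),
        "n_measurements": int(len(ga)),
        "n_ptb_pos": int(ptb_flags.sum()),
    }


def write_cohort_csv(recordings, path) -> None:
    """Write recordings as long-format CSV (patient_id, timestamp, activity, light)."""
    frames = []
    for rec in recordings:
        ts = pd.date_range(rec.start_time, periods=rec.length, freq="1min")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": rec.patient_id,
                    "timestamp": ts,
                    "activity": rec.activity,
                    "light": rec.light if rec.light is not None else np.nan,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)
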