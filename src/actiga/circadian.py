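"""Sleep/wake annotation and nonparametric circadian summary metrics.

Implements the device-standard Oakley weighted-moving-sum sleep scorer and
the classic nonparametric actigraphy statistics: interdaily stability (IS),
intradaily variability (IV), relative amplitude (RA = (M10-L5)/(M10+L5))
plus weekly rest/activity summaries stratified by sleep state and
weekday/weekend.

All metrics operate on the raw activity-count channel at 1-min epochs; IS is
computed on hourly bins by convention, IV on the native resolution unless a
bin width is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import UndefinedMetricError

MINUTES_PER_DAY = 1440
#: Oakley weights for 1-min epochs, centred on the scored epoch.
OAKLEY_WEIGHTS = (0.04, 0.20, 1.0, 0.20, 0.04)
OAKLEY_THRESHOLD = 80.0


@dataclass
class CircadianSummary:
    """Per-measurement circadian and activity summary (one Table-style row)."""

    IS: float
    IV: float
    RA: float
    M10: float
    L5: float
    minutes_rest: float
    mean_activity_wake: float
    mean_activity_sleep: float
    mean_activity_weekday: float
    mean_activity_weekend: float
    ISm: Optional[float] = None
    IVm: Optional[float] = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def oakley_sleep_wake(activity: Sequence[float], threshold: float = OAKLEY_THRESHOLD) -> np.ndarray:
    """Score each 1-min epoch as sleep (1) or wake (0) by the Oakley method.

    The weighted score is
    ``s_t = 0.04*(a[t-2]+a[t+2]) + 0.20*(a[t-1]+a[t+1]) + 1.0*a[t]``
    with zero padding at the ends; an epoch is sleep iff ``s_t < threshold``.
    """
    a = np.asarray(activity, dtype=float)
    if a.ndim != 1:
        raise ValueError("activity must be 1-D")
    if a.size < 5:
        raise ValueError("Oakley scoring needs at least 5 epochs")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    padded = np.pad(a, 2)
    w = np.array(OAKLEY_WEIGHTS)
    score = (
        w[0] * (padded[:-4] + padded[4:])
        + w[1] * (padded[1:-3] + padded[3:-1])
        + w[2] * a
    )
    return (score < threshold).astype(np.int8)


def _bin_means(a: np.ndarray, width: int) -> np.ndarray:
    n = a.size - a.size % width
    return a[:n].reshape(-1, width).mean(axis=1)


def interdaily_stability(activity: Sequence[float], bin_minutes: int = 60) -> float:
    """IS: fraction of total variance explained by the average 24-h profile.

    ``IS = (N * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2)`` where
    the series is binned at `bin_minutes` and ``p`` bins cover one day.
    Near 1 for a perfectly repeating day, near 0 for arrhythmic data.
    """
    a = np.asarray(activity, dtype=float)
    if a.size == 0 or a.size % MINUTES_PER_DAY != 0:
        raise ValueError("IS needs whole days of 1-min data (length divisible by 1440)")
    if MINUTES_PER_DAY % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440")
    x = _bin_means(a, bin_minutes)
    p = MINUTES_PER_DAY // bin_minutes
    n = x.size
    xbar = x.mean()
    total = np.sum((x - xbar) ** 2)
    if total == 0:
        raise UndefinedMetricError("IS undefined for constant activity")
    hourly = x.reshape(-1, p).mean(axis=0)
    return float(n * np.sum((hourly - xbar) ** 2) / (p * total))


def intradaily_variability(activity: Sequence[float], bin_minutes: int = 1) -> float:
    """IV: normalized first-difference variance, in [0, 4].

    ``IV = (N * sum (x_i - x_{i-1})^2) / ((N-1) * sum (x_i - xbar)^2)``.
    0 for a smooth series, ~2 for white noise, 4 for maximal alternation.
    """
    a = np.asarray(activity, dtype=float)
    if bin_minutes > 1:
        a = _bin_means(a, bin_minutes)
    n = a.size
    if n < 2:
        raise ValueError("IV needs at least 2 epochs")
    xbar = a.mean()
    total = np.sum((a - xbar) ** 2)
    if total == 0:
        raise UndefinedMetricError("IV undefined for constant activity")
    return float(n * np.sum(np.diff(a) ** 2) / ((n - 1) * total))


def mean_binned_is_iv(activity: Sequence[float], widths: Optional[Sequence[int]] = None) -> tuple[float, float]:
    """ISm/IVm: IS and IV averaged over a schedule of bin widths (1..60 min).

    Uses every width up to 60 min that divides the day evenly.
    """
    if widths is None:
        widths = [w for w in range(1, 61) if MINUTES_PER_DAY % w == 0]
    a = np.asarray(activity, dtype=float)
    is_vals, iv_vals = [], []
    for w in widths:
        is_vals.append(interdaily_stability(a, bin_minutes=w))
        iv_vals.append(intradaily_variability(a, bin_minutes=w))
    return float(np.mean(is_vals)), float(np.mean(iv_vals))


def relative_amplitude(activity: Sequence[float]) -> tuple[float, float, float]:
    """(M10, L5, RA) from the average 24-h hourly profile.

    M10/L5 are the means of the best contiguous 10-h / 5-h windows of the
    average day (circular wrap-around); RA = (M10-L5)/(M10+L5).
    """
    a = np.asarray(activity, dtype=float)
    if a.size == 0 or a.size % MINUTES_PER_DAY != 0:
        raise ValueError("RA needs whole days of 1-min data")
    hourly = _bin_means(a, 60).reshape(-1, 24).mean(axis=0)
    wrapped = np.concatenate([hourly, hourly])
    win10 = np.array([wrapped[s : s + 10].mean() for s in range(24)])
    win5 = np.array([wrapped[s : s + 5].mean() for s in range(24)])
    m10 = float(win10.max())
    l5 = float(win5.min())
    if m10 + l5 == 0:
        raise UndefinedMetricError("RA undefined: M10 + L5 = 0")
    return m10, l5, float((m10 - l5) / (m10 + l5))


def activity_summaries(
    signal: np.ndarray,
    sleep_mask: np.ndarray,
    start_weekday: int = 0,
) -> dict:
    """Weekly rest minutes and stratified mean activities.

    `signal` is the (possibly log-scale) activity vector; `sleep_mask` is the
    aligned binary sleep vector; `start_weekday` is the day-of-week of the
    first epoch (0=Monday .. 6=Sunday). Empty strata yield NaN means.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim == 2:  # accept a 2xL sample matrix; activity is channel 0
        x = x[0]
    mask = np.asarray(sleep_mask).astype(bool)
    if mask.shape != x.shape:
        raise ValueError("sleep_mask must align with the activity signal")

    def _mean(values: np.ndarray) -> float:
        return float(values.mean()) if values.size else float("nan")

    n_days = int(np.ceil(x.size / MINUTES_PER_DAY))
    day_of_week = (start_weekday + np.arange(n_days)) % 7
    weekend_days = np.isin(day_of_week, (5, 6))
    weekend_epochs = np.repeat(weekend_days, MINUTES_PER_DAY)[: x.size]

    return {
        "minutes_rest": float(mask.sum()),
        "mean_activity_wake": _mean(x[~mask]),
        "mean_activity_sleep": _mean(x[mask]),
        "mean_activity_weekday": _mean(x[~weekend_epochs]),
        "mean_activity_weekend": _mean(x[weekend_epochs]),
    }


def circadian_summary(
    activity_counts: np.ndarray,
    log_signal: np.ndarray,
    sleep_mask: np.ndarray,
    start_weekday: int = 0,
    with_multibin: bool = False,
) -> CircadianSummary:
    """Full summary row: IS/IV/RA on raw counts, means on the log-scale signal."""
    m10, l5, ra = relative_amplitude(activity_counts)
    sums = activity_summaries(log_signal, sleep_mask, start_weekday)
    ism = ivm = None
    if with_multibin:
        ism, ivm = mean_binned_is_iv(activity_counts)
    return CircadianSummary(
        IS=interdaily_stability(activity_counts),
        IV=intradaily_variability(activity_counts),
        RA=ra,
        M10=m10,
        L5=l5,
        ISm=ism,
        IVm=ivm,
        **sums,
    )
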