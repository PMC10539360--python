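"""Time-series augmentation operators, selection schemes and TTA inference.

Five operators — none, jitter (additive Gaussian noise, sigma=0.03), scaling
(one multiplicative alpha ~ N(1, 0.2^2) per channel), window warping (a
random 10% window stretched/compressed by a factor of 2 or 1/2, then the
whole series re-interpolated to its original length) and slicing (a random
contiguous 90% crop re-interpolated to full length). Rotation is
deliberately excluded. A scheme either draws one random operator
(random_one) or applies all in random order (all), refreshed per epoch or
per mini-batch; at inference the prediction is averaged over the operator
set (test-time augmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

OPERATOR_NAMES = ("none", "jitter", "scaling", "window_warp", "slicing")


@dataclass
class AugmentationParams:
    sigma_jitter: float = 0.03
    mu_scale: float = 1.0
    sigma_scale: float = 0.2
    warp_window_frac: float = 0.10
    warp_factors: tuple = (2.0, 0.5)
    slice_frac: float = 0.90


@dataclass
class AugmentationScheme:
    operators: tuple = OPERATOR_NAMES
    selection: str = "random_one"  # or "all"
    granularity: str = "per_epoch"  # or "per_batch"
    params: AugmentationParams = field(default_factory=AugmentationParams)
    seed: int = 0

    def __post_init__(self):
        if not self.operators:
            raise ValueError("operator set must be non-empty")
        unknown = set(self.operators) - set(OPERATOR_NAMES)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")
        if self.selection not in ("random_one", "all"):
            raise ValueError("selection must be 'random_one' or 'all'")
        if self.granularity not in ("per_epoch", "per_batch"):
            raise ValueError("granularity must be 'per_epoch' or 'per_batch'")
        p = self.params
        if not (0 < p.warp_window_frac <= 1 and 0 < p.slice_frac <= 1):
            raise ValueError("window fractions must lie in (0, 1]")


def jitter(signal: np.ndarray, sigma: float = 0.03, rng=None) -> np.ndarray:
    """Add i.i.d. N(0, sigma^2) noise elementwise."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(signal, dtype=float)
    if sigma == 0:
        return x.copy()
    return x + rng.normal(0.0, sigma, size=x.shape)


def scaling(signal: np.ndarray, mu: float = 1.0, sigma: float = 0.2, rng=None) -> np.ndarray:
    """Multiply each channel by one alpha ~ N(mu, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    alpha = rng.normal(mu, sigma, size=(x.shape[0], 1))
    out = x * alpha
    return out.reshape(np.asarray(signal).shape)


def _resample(x: np.ndarray, new_len: int) -> np.ndarray:
    """Linear re-interpolation of each channel to `new_len` points."""
    old = np.linspace(0.0, 1.0, x.shape[-1])
    new = np.linspace(0.0, 1.0, new_len)
    return np.stack([np.interp(new, old, ch) for ch in np.atleast_2d(x)])


def window_warp(
    signal: np.ndarray,
    window_frac: float = 0.10,
    factors: Sequence[float] = (2.0, 0.5),
    rng=None,
) -> np.ndarray:
    """Stretch/compress a random window, re-interpolate back to length L."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    L = x.shape[-1]
    if L < 10:
        raise ValueError("series too short to window-warp")
    w = max(int(round(window_frac * L)), 2)
    start = int(rng.integers(0, L - w + 1))
    factor = float(factors[int(rng.integers(0, len(factors)))])
    warped_len = max(int(round(w * factor)), 2)
    segment = _resample(x[:, start : start + w], warped_len)
    out = np.concatenate([x[:, :start], segment, x[:, start + w :]], axis=-1)
    out = _resample(out, L)
    return out.reshape(np.asarray(signal).shape)


def slicing(signal: np.ndarray, keep_frac: float = 0.90, rng=None) -> np.ndarray:
    """Keep a random contiguous `keep_frac` crop, re-interpolated to length L."""
    if not 0 < keep_frac < 1:
        raise ValueError("keep_frac must lie in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    L = x.shape[-1]
    w = max(int(round(keep_frac * L)), 2)
    start = int(rng.integers(0, L - w + 1))
    out = _resample(x[:, start : start + w], L)
    return out.reshape(np.asarray(signal).shape)


def _apply_one(name: str, x: np.ndarray, params: AugmentationParams, rng) -> np.ndarray:
    if name == "none":
        return np.asarray(x, dtype=float).copy()
    if name == "jitter":
        return jitter(x, params.sigma_jitter, rng)
    if name == "scaling":
        return scaling(x, params.mu_scale, params.sigma_scale, rng)
    if name == "window_warp":
        return window_warp(x, params.warp_window_frac, params.warp_factors, rng)
    if name == "slicing":
        return slicing(x, params.slice_frac, rng)
    raise ValueError(f"unknown operator {name!r}")


def apply_operators(signal, names: Sequence[str], params: AugmentationParams = None, rng=None):
    """Apply an ordered list of operators to one signal."""
    params = params or AugmentationParams()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.asarray(signal, dtype=float)
    for name in names:
        out = _apply_one(name, out, params, rng)
    return out


def draw_augmentation(scheme: AugmentationScheme, epoch_index: int, batch_index: int = 0):
    """Ordered operator list for this (epoch, batch) under the scheme.

    The draw is a pure function of (scheme.seed, epoch) for per_epoch
    granularity — every batch of an epoch gets the same operators — and of
    (scheme.seed, epoch, batch) for per_batch.
    """
    if scheme.granularity == "per_epoch":
        key = (scheme.seed, epoch_index)
    else:
        key = (scheme.seed, epoch_index, batch_index)
    rng = np.random.default_rng(np.random.PCG64(list(key)))
    ops = list(scheme.operators)
    if scheme.selection == "random_one":
        return [ops[int(rng.integers(0, len(ops)))]]
    perm = rng.permutation(len(ops))
    return [ops[i] for i in perm]


def tta_predict(
    predict_fn: Callable,
    signal: np.ndarray,
    operators: Sequence[str] = OPERATOR_NAMES,
    params: AugmentationParams = None,
    seed: int = 0,
    n_draws: int = 1,
) -> float:
    """Test-time augmentation: average `predict_fn` over transformed copies.

    Stochastic operators are drawn `n_draws` times each with a fixed seed so
    the averaged prediction is reproducible.
    """
    params = params or AugmentationParams()
    rng = np.random.default_rng(seed)
    preds = []
    for name in operators:
        draws = 1 if name == "none" else n_draws
        for _ in range(draws):
            preds.append(float(predict_fn(apply_operators(signal, [name], params, rng))))
    return float(np.mean(preds))
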