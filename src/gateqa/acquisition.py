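"""Optical surface-tracking emulation.

A stereo-camera surface tracker does not sample on a fixed clock: the
instantaneous frame rate wanders around its mean (here 22.7 ± 0.5 Hz by
default). This module resamples a ground-truth trace on such an irregular
clock, optionally applies a constant tracking lag, and adds i.i.d.
Gaussian position noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .breathing import BreathingTrace

__all__ = ["AcquisitionModel", "sample_trace", "rate_histogram"]


@dataclass(frozen=True)
class AcquisitionModel:
    """Camera sampling model: irregular rate, position noise, tracking lag."""

    rate_mean: float = 22.7  # Hz
    rate_sd: float = 0.5  # Hz
    noise_sd: float = 0.0  # mm
    lag: float = 0.0  # s, constant tracking delay
    rate_floor: float = 5.0  # Hz, truncation of the instantaneous rate
    rate_cap: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if self.rate_mean <= 0:
            raise ValueError("rate_mean must be > 0")
        if self.rate_sd < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if not (0 < self.rate_floor <= self.rate_mean <= self.rate_cap):
            raise ValueError("rate truncation must bracket the mean")


def _draw_rates(model: AcquisitionModel, size: int,
                rng: np.random.Generator) -> np.ndarray:
    if model.rate_sd == 0:
        return np.full(size, model.rate_mean)
    a = (model.rate_floor - model.rate_mean) / model.rate_sd
    b = (model.rate_cap - model.rate_mean) / model.rate_sd
    return stats.truncnorm.rvs(a, b, loc=model.rate_mean, scale=model.rate_sd,
                               size=size, random_state=rng)


def sample_trace(truth: BreathingTrace, model: AcquisitionModel,
                 seed: Optional[int] = None) -> BreathingTrace:
    """Resample a ground-truth trace through the camera model.

    Successive sample intervals are the reciprocals of truncated-normal
    instantaneous rates; values are linearly interpolated from the truth at
    (t − lag) and perturbed with independent Gaussian noise.
    """
    if len(truth) == 0:
        raise ValueError("truth trace is empty")
    if truth.duration <= 2.0 / model.rate_mean:
        raise ValueError("truth trace too short for the sampling rate")
    if model.lag >= truth.duration:
        raise ValueError("tracking lag exceeds trace duration")

    rng = np.random.default_rng(seed)
    t0 = truth.times[0] + model.lag
    t_end = truth.times[-1]
    # draw more intervals than needed, then trim
    n_guess = int(np.ceil((t_end - t0) * model.rate_cap)) + 2
    dts = 1.0 / _draw_rates(model, n_guess, rng)
    times = t0 + np.concatenate([[0.0], np.cumsum(dts)])
    times = times[times <= t_end]
    values = truth.interp(times - model.lag)
    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, size=times.size)
    return BreathingTrace(times, values, kind="measured",
                          meta={"model": model, "seed": seed})


def rate_histogram(measured: BreathingTrace,
                   bins: int = 30) -> Tuple[float, float, np.ndarray, np.ndarray]:
    """Instantaneous sampling-rate statistics of a measured trace.

    Returns (mean Hz, sample SD Hz, bin counts, bin edges), where the
    instantaneous rates are the reciprocals of successive time differences.
    """
    if len(measured) < 3:
        raise ValueError("need at least 3 samples for a rate histogram")
    rates = 1.0 / np.diff(measured.times)
    counts, edges = np.histogram(rates, bins=bins)
    sd = float(np.std(rates, ddof=1))
    return float(np.mean(rates)), sd, counts, edges
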