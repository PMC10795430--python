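"""Ground-truth breathing waveforms.

Analytic cos⁴ breathing patterns — the standard idealised waveform for
respiratory-motion phantoms, spending most of each cycle near end-exhale —
and volunteer-like patterns built by re-scaling one cos⁴ cycle template to
per-cycle amplitudes and periods drawn from specified moments.

Sign convention: displacement is measured from the end-exhale baseline,
positive toward inhale, so the end-exhale extremum sits at ``baseline`` and
the inhale peak at ``baseline + A``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Cos4Spec",
    "JitteredSpec",
    "BreathingTrace",
    "eval_cos4",
    "max_speed_cos4",
    "generate_pattern",
    "read_trace",
    "write_trace",
]

#: default ground-truth sample rate, Hz; at least 4x the camera rate so the
#: truth grid dominates interpolation error in downstream comparisons
DEFAULT_TRUTH_RATE = 100.0


@dataclass(frozen=True)
class Cos4Spec:
    """Deterministic cos⁴ breathing pattern.

    Parameters
    ----------
    amplitude : float
        Peak-to-peak displacement A, mm.
    period : float
        Breathing period T, s.
    duration : float
        Trace length, s.
    baseline : float
        Displacement of the end-exhale minimum, mm.
    """

    amplitude: float
    period: float
    duration: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass(frozen=True)
class JitteredSpec:
    """Volunteer-like pattern: per-cycle amplitude/period jitter.

    Each cycle is a cos⁴ template rescaled to that cycle's sampled
    peak-to-peak amplitude and period, drawn from truncated normals with the
    given moments. Cycles are concatenated at the end-exhale minima, which
    guarantees value continuity regardless of the per-cycle amplitudes.
    """

    amplitude_mean: float
    amplitude_sd: float
    period_mean: float
    period_sd: float
    n_cycles: int
    baseline: float = 0.0
    #: truncation floor for sampled amplitudes, mm
    amplitude_floor: float = 0.1
    #: truncation floor for sampled periods, s
    period_floor: float = 0.5
    #: half-width of the truncation interval in units of the SD
    truncation_sds: float = 3.0

    def __post_init__(self) -> None:
        if self.amplitude_mean <= 0 or self.period_mean <= 0:
            raise ValueError("means must be > 0")
        if self.amplitude_sd < 0 or self.period_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")


@dataclass
class BreathingTrace:
    """Time-stamped 1-D displacement signal, mm vs s."""

    times: np.ndarray
    displacements: np.ndarray
    kind: str = "truth"  # "truth" | "measured"
    cycles: Optional[pd.DataFrame] = None
    status: str = "ok"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.times.shape != self.displacements.shape:
            raise ValueError("times and displacements must have equal length")
        if self.times.size:
            if not np.all(np.isfinite(self.times)) or not np.all(
                np.isfinite(self.displacements)
            ):
                raise ValueError("trace values must be finite")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the displacement at times ``t``."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.displacements)


def eval_cos4(spec: Cos4Spec, times: np.ndarray) -> np.ndarray:
    """Evaluate x(t) = baseline + A·cos⁴(π t / T).

    The waveform peaks at t = 0 (A above baseline) and reaches the
    end-exhale baseline at t = T/2; it is periodic with period T.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    return spec.baseline + spec.amplitude * np.cos(np.pi * t / spec.period) ** 4


def max_speed_cos4(amplitude: float, period: float) -> float:
    """Maximum speed of the cos⁴ waveform over one period, mm/s.

    |dx/dt| = (4πA/T)·|cos³u sin u| with u = πt/T is maximised at
    tan²u = 1/3, giving V_max = A·(4π/T)·(3√3/16) = (3√3π/4)·A/T.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if period <= 0:
        raise ValueError("period must be > 0")
    return float(amplitude * (4.0 * np.pi / period) * (3.0 * np.sqrt(3.0) / 16.0))


def _truncnorm(mean: float, sd: float, floor: float, n_sds: float,
               size: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal draws on [max(mean - n_sds*sd, floor), mean + n_sds*sd]."""
    if sd == 0:
        return np.full(size, mean)
    lo = max(mean - n_sds * sd, floor)
    hi = mean + n_sds * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _jittered_trace(spec: JitteredSpec, sample_rate: float,
                    rng: np.random.Generator) -> BreathingTrace:
    amps = _truncnorm(spec.amplitude_mean, spec.amplitude_sd,
                      spec.amplitude_floor, spec.truncation_sds, spec.n_cycles, rng)
    pers = _truncnorm(spec.period_mean, spec.period_sd,
                      spec.period_floor, spec.truncation_sds, spec.n_cycles, rng)

    # Segment layout: a leading descending half-cycle (peak -> end-exhale
    # minimum, using cycle 1's parameters) followed by n full min-to-min
    # cycles.  With zero SDs this reduces exactly to the cos4 waveform.
    lead = pers[0] / 2.0
    starts = lead + np.concatenate([[0.0], np.cumsum(pers[:-1])])
    total = lead + float(np.sum(pers))

    times = np.arange(0.0, total, 1.0 / sample_rate)
    x = np.empty_like(times)
    head = times < lead
    x[head] = amps[0] * np.cos(np.pi * times[head] / pers[0]) ** 4
    idx = np.searchsorted(starts, times, side="right") - 1
    body = ~head
    i = np.clip(idx[body], 0, spec.n_cycles - 1)
    u = np.pi * (times[body] - starts[i]) / pers[i]
    x[body] = amps[i] * np.sin(u) ** 4
    x += spec.baseline

    table = pd.DataFrame({
        "cycle": np.arange(1, spec.n_cycles + 1),
        "start_s": starts,
        "peak_time_s": starts + pers / 2.0,
        "amplitude_mm": amps,
        "period_s": pers,
    })
    return BreathingTrace(times, x, kind="truth", cycles=table)


def generate_pattern(spec: Union[Cos4Spec, JitteredSpec],
                     sample_rate: float = DEFAULT_TRUTH_RATE,
                     seed: Optional[int] = None) -> BreathingTrace:
    """Generate a ground-truth breathing trace from a pattern spec.

    Returns a :class:`BreathingTrace` with a per-cycle table (cycle index,
    amplitude, period). For a degenerate spec (zero duration or zero
    cycles) an empty trace with ``status='empty'`` is returned.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")

    if isinstance(spec, Cos4Spec):
        if spec.duration == 0:
            return BreathingTrace(np.array([]), np.array([]), status="empty")
        times = np.arange(0.0, spec.duration, 1.0 / sample_rate)
        x = eval_cos4(spec, times)
        n_cycles = int(spec.duration // spec.period)
        table = pd.DataFrame({
            "cycle": np.arange(1, n_cycles + 1),
            "start_s": spec.period / 2.0 + spec.period * np.arange(n_cycles),
            "peak_time_s": spec.period * np.arange(1, n_cycles + 1),
            "amplitude_mm": np.full(n_cycles, spec.amplitude),
            "period_s": np.full(n_cycles, spec.period),
        })
        return BreathingTrace(times, x, kind="truth", cycles=table)

    if isinstance(spec, JitteredSpec):
        if spec.n_cycles == 0:
            return BreathingTrace(np.array([]), np.array([]), status="empty")
        rng = np.random.default_rng(seed)
        return _jittered_trace(spec, sample_rate, rng)

    raise TypeError(f"unsupported spec type: {type(spec)!r}")


# ---------------------------------------------------------------------------
# trace I/O: 2-column CSV plus a JSON sidecar carrying spec and seed

def write_trace(trace: BreathingTrace, path: Union[str, Path],
                sidecar: Optional[dict] = None) -> None:
    path = Path(path)
    pd.DataFrame({
        "time_s": trace.times,
        "displacement_mm": trace.displacements,
    }).to_csv(path, index=False)
    meta = {"kind": trace.kind, "status": trace.status}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_trace(path: Union[str, Path]) -> BreathingTrace:
    path = Path(path)
    df = pd.read_csv(path)
    kind = "truth"
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.get("kind", kind)
    return BreathingTrace(df["time_s"].to_numpy(),
                          df["displacement_mm"].to_numpy(), kind=kind, meta=meta)
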