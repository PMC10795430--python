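"""Amplitude-window respiratory gating with latency.

Models a surface-guidance gating workflow: the CT scanner and the gating
software describe the same breathing curve on different phase scales, the
gate opens/closes when the tracked signal crosses amplitude thresholds
derived from the window (after a learning period that establishes baseline
and amplitude), and the accelerator reacts with finite beam-on/off delays.

Phase conventions
-----------------
* CT convention: inhale 0–100% and exhale 0–100% as two separate branches.
* Gating-software convention: one scale with the inhale peak at 100% and
  the end-exhale minimum at 50%, so a CT percentage maps to half its value
  on the corresponding branch (20% CT ↔ 10% branch-relative).

Window conventions
------------------
``amplitude_threshold`` (default): the window bounds are fractions of the
learned peak-to-peak amplitude; the gate opens when the descending signal
drops below the exhale-bound threshold and closes when the ascending signal
rises above the inhale-bound threshold. ``time_phase``: the gate is on
while the linear-in-time phase of the cycle lies inside the mapped window.
The amplitude convention is the default because it reproduces the measured
duty cycle and residual motion of a cos⁴ pattern; a linear-time window
would give a 50% duty cycle and a far larger residual motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Tuple

import numpy as np

from .breathing import BreathingTrace
from .signal_metrics import detect_cycles

__all__ = [
    "GateWindow",
    "GateSignal",
    "LatencyModel",
    "PhaseMapping",
    "ct_to_gatert",
    "window_thresholds",
    "gate_signal",
    "apply_latency",
    "duty_cycle",
    "residual_motion",
    "write_gate",
    "read_gate",
]


class PhaseMapping(NamedTuple):
    absolute_pct: float
    branch_relative_pct: float


def ct_to_gatert(ct_pct: float, branch: str) -> PhaseMapping:
    """Map a CT-convention phase percentage to the gating-software scale.

    The exhale branch spans 0→50% absolute (peak to trough), the inhale
    branch 50→100% (trough to peak); branch-relative values are half the
    CT percentage on either branch.
    """
    if not 0.0 <= ct_pct <= 100.0:
        raise ValueError("CT percentage must be in [0, 100]")
    rel = ct_pct / 2.0
    if branch == "exhale":
        return PhaseMapping(rel, rel)
    if branch == "inhale":
        return PhaseMapping(50.0 + rel, rel)
    raise ValueError(f"unknown branch: {branch!r}")


@dataclass(frozen=True)
class GateWindow:
    """Gating window in CT convention: (exhale bound %, inhale bound %)."""

    exhale_pct: float
    inhale_pct: float
    convention: str = "amplitude_threshold"  # or "time_phase"

    def __post_init__(self) -> None:
        for v in (self.exhale_pct, self.inhale_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("window bounds must be in [0, 100]")
        if self.convention not in ("amplitude_threshold", "time_phase"):
            raise ValueError(f"unknown convention: {self.convention!r}")

    @classmethod
    def from_gatert(cls, exhale_abs_pct: float, inhale_abs_pct: float,
                    convention: str = "amplitude_threshold") -> "GateWindow":
        """Build a window from absolute gating-software percentages
        (exhale bound in [0, 50], inhale bound in [50, 100])."""
        if not (0 <= exhale_abs_pct <= 50 <= inhale_abs_pct <= 100):
            raise ValueError("absolute bounds must satisfy 0<=ex<=50<=in<=100")
        return cls(exhale_abs_pct * 2.0, (inhale_abs_pct - 50.0) * 2.0,
                   convention)


@dataclass(frozen=True)
class LatencyModel:
    """Beam reaction delays after a gate transition, s."""

    beam_on_delay: float = 0.0
    beam_off_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.beam_on_delay < 0 or self.beam_off_delay < 0:
            raise ValueError("delays must be >= 0")


@dataclass
class GateSignal:
    """Ordered disjoint (on, off) intervals plus learning metadata.

    ``steady`` flags intervals that both opened and closed on a genuine
    threshold crossing (the last interval may instead be clipped by the end
    of the trace); steady intervals are the ones used for duty-cycle and
    residual-motion statistics.
    """

    intervals: np.ndarray  # shape (N, 2)
    learning_end: float = 0.0
    window: Optional[GateWindow] = None
    steady: Optional[np.ndarray] = None
    status: str = "ok"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if self.steady is None:
            self.steady = np.ones(len(self.intervals), dtype=bool)
        if len(self.intervals):
            if np.any(self.intervals[:, 0] >= self.intervals[:, 1]):
                raise ValueError("intervals must satisfy on < off")
            if np.any(np.diff(self.intervals.ravel()) < 0):
                raise ValueError("intervals must be disjoint and increasing")

    def __len__(self) -> int:
        return len(self.intervals)

    def steady_intervals(self) -> np.ndarray:
        """Intervals usable for steady-state statistics (falls back to all
        intervals when none closed on a crossing, e.g. an always-on gate)."""
        sel = self.intervals[self.steady]
        return sel if len(sel) else self.intervals

    def is_on(self, t: np.ndarray) -> np.ndarray:
        """Boolean beam/gate state at times ``t``."""
        t = np.asarray(t, dtype=float)
        if len(self.intervals) == 0:
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self.intervals.ravel(), t, side="right")
        return idx % 2 == 1


def window_thresholds(window: GateWindow, amplitude: float) -> Tuple[float, float]:
    """Amplitude thresholds (open, close) in mm above the end-exhale
    baseline: open on the descending branch at exhale%·A, close on the
    ascending branch at inhale%·A."""
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    return (window.exhale_pct / 100.0 * amplitude,
            window.inhale_pct / 100.0 * amplitude)


def _crossing_time(t0, t1, x0, x1, level):
    if x1 == x0:
        return t0
    return t0 + (level - x0) * (t1 - t0) / (x1 - x0)


def _amplitude_gate(trace: BreathingTrace, open_level: float, close_level: float,
                    t_start: float) -> list:
    """Threshold state machine on interpolated crossings, from t_start."""
    t, x = trace.times, trace.displacements
    down = np.nonzero((x[:-1] >= open_level) & (x[1:] < open_level))[0]
    up = np.nonzero((x[:-1] <= close_level) & (x[1:] > close_level))[0]
    events = sorted(
        [(_crossing_time(t[i], t[i + 1], x[i], x[i + 1], open_level), "on")
         for i in down] +
        [(_crossing_time(t[i], t[i + 1], x[i], x[i + 1], close_level), "off")
         for i in up])

    intervals = []
    state_on = False
    t_on = None
    for tc, kind in events:
        if tc < t_start:
            continue
        if kind == "on" and not state_on:
            state_on, t_on = True, tc
        elif kind == "off" and state_on:
            state_on = False
            intervals.append((t_on, tc, True))
    if state_on and t[-1] > t_on:
        intervals.append((t_on, t[-1], False))  # clipped by trace end
    return intervals


def _phase_gate(trace: BreathingTrace, window: GateWindow, peak_times: np.ndarray,
                t_start: float) -> list:
    """Linear-in-time phase window: peak = 0%, trough = 50%, next peak = 100%."""
    lo = ct_to_gatert(window.exhale_pct, "exhale").absolute_pct
    hi = ct_to_gatert(window.inhale_pct, "inhale").absolute_pct
    intervals = []
    for ta, tb in zip(peak_times[:-1], peak_times[1:]):
        cycle = tb - ta
        on = ta + lo / 100.0 * cycle
        off = ta + hi / 100.0 * cycle
        if on >= t_start and off > on:
            intervals.append((on, off, True))
    return intervals


def gate_signal(trace: BreathingTrace, window: GateWindow,
                learning_cycles: int = 3,
                min_gate_duration: float = 0.1) -> GateSignal:
    """Build the gate on/off signal for a breathing trace.

    The first ``learning_cycles`` detected cycles are the learning period:
    the end-exhale baseline is the mean of their valley values and the
    working amplitude the mean of their peak-to-peak amplitudes. Gate
    intervals begin only after the learning period; intervals shorter than
    ``min_gate_duration`` (debounce against noise chatter at the
    thresholds) are removed.
    """
    if len(trace) == 0 or np.ptp(trace.displacements) == 0:
        raise ValueError("flat or empty trace cannot be gated")
    table = detect_cycles(trace)
    if len(table) < learning_cycles + 1:
        raise ValueError(
            f"trace must span > {learning_cycles + 1} cycles "
            f"(found {len(table)} peaks)")

    learn = table.frame.iloc[:learning_cycles]
    valley_vals = trace.interp(learn["valley_time_s"].to_numpy())
    baseline = float(np.mean(valley_vals))
    amplitude = float(np.mean(learn["amplitude_mm"]))
    # learning ends at the first post-learning peak (e.g. the fourth peak
    # for a 3-cycle learning period)
    learning_end = float(table.frame["peak_time_s"].iloc[learning_cycles])

    if window.convention == "amplitude_threshold":
        open_thr, close_thr = window_thresholds(window, amplitude)
        if open_thr == 0.0:
            # the open threshold sits exactly on the end-exhale baseline:
            # the signal cannot descend strictly below its own minimum
            raw = []
        else:
            raw = _amplitude_gate(trace, baseline + open_thr,
                                  baseline + close_thr, learning_end)
    else:
        raw = _phase_gate(trace, window,
                          table.frame["peak_time_s"].to_numpy(), learning_end)

    kept = [(a, b, s) for a, b, s in raw if b - a >= min_gate_duration]
    if not kept:
        return GateSignal(np.empty((0, 2)), learning_end, window,
                          steady=np.empty(0, dtype=bool),
                          status="never_crossed",
                          meta={"baseline": baseline, "amplitude": amplitude})
    ivals = np.array([(a, b) for a, b, _ in kept])
    steady = np.array([s for _, _, s in kept], dtype=bool)
    return GateSignal(ivals, learning_end, window, steady=steady,
                      meta={"baseline": baseline, "amplitude": amplitude})


def apply_latency(gate: GateSignal, latency: LatencyModel) -> GateSignal:
    """Shift each on-transition by the beam-on delay and each off-transition
    by the beam-off delay; intervals that become non-positive are dropped
    and any resulting overlaps merged."""
    if len(gate) == 0:
        return GateSignal(np.empty((0, 2)), gate.learning_end, gate.window,
                          steady=np.empty(0, dtype=bool), status=gate.status)
    shifted = gate.intervals + np.array([latency.beam_on_delay,
                                         latency.beam_off_delay])
    keep = shifted[:, 1] > shifted[:, 0]
    shifted, steady = shifted[keep], gate.steady[keep]
    merged, merged_steady = [], []
    for (a, b), s in zip(shifted, steady):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
            merged_steady[-1] = merged_steady[-1] and s
        else:
            merged.append([a, b])
            merged_steady.append(bool(s))
    return GateSignal(np.array(merged), gate.learning_end, gate.window,
                      steady=np.array(merged_steady, dtype=bool),
                      status=gate.status if merged else "dropped",
                      meta=dict(gate.meta, latency=latency))


def duty_cycle(gate: GateSignal, period: float) -> Tuple[float, float]:
    """(on-fraction of the breathing period, mean on-interval duration s)
    over steady-state intervals. An empty gate gives (0, 0); a gate that
    never closes (always on) saturates at fraction 1."""
    if period <= 0:
        raise ValueError("period must be > 0")
    if len(gate) == 0:
        return 0.0, 0.0
    ivals = gate.steady_intervals()
    mean_dur = float(np.mean(ivals[:, 1] - ivals[:, 0]))
    return min(mean_dur / period, 1.0), mean_dur


def write_gate(gate: GateSignal, path) -> None:
    """Export the gate intervals as a two-column CSV (on_s, off_s)."""
    import pandas as pd

    pd.DataFrame(gate.intervals, columns=["on_s", "off_s"]).to_csv(
        path, index=False)


def read_gate(path) -> GateSignal:
    import pandas as pd

    df = pd.read_csv(path)
    return GateSignal(df[["on_s", "off_s"]].to_numpy())


def residual_motion(trace: BreathingTrace, gate: GateSignal) -> float:
    """Peak-to-peak displacement occurring while the gate is on, mm.

    Max minus min of the displacement over all steady-state on-intervals,
    including the interpolated values at the interval endpoints (the
    threshold-crossing positions)."""
    if len(gate) == 0:
        return 0.0
    lo, hi = np.inf, -np.inf
    for a, b in gate.steady_intervals():
        sel = (trace.times >= a) & (trace.times <= b)
        vals = np.concatenate([trace.displacements[sel], trace.interp([a, b])])
        lo = min(lo, float(vals.min()))
        hi = max(hi, float(vals.max()))
    return hi - lo
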