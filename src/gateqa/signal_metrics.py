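"""Trace-comparison analytics.

Cycle detection on breathing traces, per-cycle amplitude/period summaries,
anchored synchronization of a measured trace against its ground truth, and
the two agreement statistics used to qualify a surface tracker: the mean
absolute deviation (MAD, mm) and the Pearson correlation coefficient (PCC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .breathing import BreathingTrace

__all__ = [
    "CycleTable",
    "CycleSummary",
    "AlignedPair",
    "detect_cycles",
    "summarize_cycles",
    "synchronize",
    "mad",
    "pcc",
]


@dataclass
class CycleTable:
    """Per-cycle peak/valley times, peak-to-peak amplitude and period.

    ``frame`` columns: peak_time_s, valley_time_s, amplitude_mm, period_s.
    The period of the last detected cycle is NaN (no successor peak).
    """

    frame: pd.DataFrame
    status: str = "ok"

    def __len__(self) -> int:
        return len(self.frame)


class CycleSummary(NamedTuple):
    amplitude_mean: float
    amplitude_sd: float
    period_mean: float
    period_sd: float


@dataclass
class AlignedPair:
    """Truth and measured signals interpolated onto a common time grid."""

    times: np.ndarray
    truth: np.ndarray
    measured: np.ndarray
    shift_s: float = 0.0
    anchor: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.truth) == len(self.measured)):
            raise ValueError("aligned arrays must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("grid must be strictly increasing")


def _find_extrema(trace: BreathingTrace, min_prominence: Optional[float],
                  min_separation: Optional[float]):
    x = trace.displacements
    if min_prominence is None:
        rng = float(np.ptp(x))
        min_prominence = 0.1 * rng if rng > 0 else np.inf
    dt = float(np.median(np.diff(trace.times)))

    def _peaks(sig, separation):
        dist = max(int(round(separation / dt)), 1) if separation else None
        idx, _ = find_peaks(sig, prominence=min_prominence, distance=dist)
        return idx

    peaks = _peaks(x, min_separation)
    if min_separation is None and len(peaks) >= 2:
        # second pass: separation = half the median peak spacing
        est = float(np.median(np.diff(trace.times[peaks])))
        peaks = _peaks(x, 0.5 * est)
        valleys = _peaks(-x, 0.5 * est)
    else:
        valleys = _peaks(-x, min_separation)
    return peaks, valleys


def detect_cycles(trace: BreathingTrace, min_prominence: Optional[float] = None,
                  min_separation: Optional[float] = None) -> CycleTable:
    """Detect breathing cycles as prominent local maxima/minima.

    Period is the spacing of successive peaks; amplitude is the peak value
    minus the mean of the adjacent valley values. Default prominence is 10%
    of the signal range; default separation is half the median peak spacing
    estimated in a first pass.
    """
    empty = pd.DataFrame(columns=["peak_time_s", "valley_time_s",
                                  "amplitude_mm", "period_s"])
    if len(trace) < 3 or np.ptp(trace.displacements) == 0:
        return CycleTable(empty, status="empty")

    peaks, valleys = _find_extrema(trace, min_prominence, min_separation)
    if len(peaks) == 0:
        return CycleTable(empty, status="empty")

    t, x = trace.times, trace.displacements
    # sub-sample refinement of the peak times: a quadratic fit over a
    # window of ~5% of the cycle averages sampling noise near the (flat)
    # peak, where the raw argmax jitters the most
    if len(peaks) >= 2:
        est_period = float(np.median(np.diff(t[peaks])))
        peak_times = np.array([
            _fit_extremum_time(trace, p, 0.05 * est_period) for p in peaks])
    else:
        peak_times = t[peaks]

    rows = []
    for k, p in enumerate(peaks):
        before = valleys[valleys < p]
        after = valleys[valleys > p]
        adjacent = [v for v in (before[-1] if len(before) else None,
                                after[0] if len(after) else None) if v is not None]
        if not adjacent:
            continue
        amp = x[p] - float(np.mean([x[v] for v in adjacent]))
        period = (peak_times[k + 1] - peak_times[k]
                  if k + 1 < len(peaks) else np.nan)
        rows.append({
            "peak_time_s": peak_times[k],
            "valley_time_s": t[adjacent[0]],
            "amplitude_mm": amp,
            "period_s": period,
        })
    if not rows:
        return CycleTable(empty, status="empty")
    return CycleTable(pd.DataFrame(rows))


def summarize_cycles(table: CycleTable) -> CycleSummary:
    """Mean and sample SD (n−1) of per-cycle amplitudes and periods."""
    if len(table) == 0:
        raise ValueError("empty cycle table")
    a = table.frame["amplitude_mm"].to_numpy()
    p = table.frame["period_s"].dropna().to_numpy()

    def _sd(v):
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    return CycleSummary(float(np.mean(a)), _sd(a),
                        float(np.mean(p)) if p.size else np.nan, _sd(p))


def _fit_extremum_time(trace: BreathingTrace, i_peak: int,
                       half_width_s: float) -> float:
    """Sub-sample peak localisation: quadratic fit over a symmetric window
    around sample ``i_peak`` (breathing peaks are locally parabolic, so
    this removes the sampling-grid quantisation and averages noise)."""
    t, x = trace.times, trace.displacements
    t0 = t[i_peak]
    sel = np.abs(t - t0) <= half_width_s
    if sel.sum() < 3:
        lo = max(i_peak - 1, 0)
        sel = np.zeros(len(t), dtype=bool)
        sel[lo:lo + 3] = True
    if sel.sum() < 3:
        return float(t0)
    a, b, _ = np.polyfit(t[sel] - t0, x[sel], 2)
    if a >= 0:  # not concave; keep the grid value
        return float(t0)
    t_star = -b / (2.0 * a)
    if abs(t_star) > np.max(np.abs(t[sel] - t0)) + 1e-12:
        return float(t0)
    return float(t0 + t_star)


def _anchor_time(trace: BreathingTrace, anchor: str) -> float:
    table = detect_cycles(trace)
    if len(table) == 0:
        raise ValueError("no peaks found for anchoring")
    peaks = table.frame
    if anchor == "fourth_peak":
        if len(peaks) < 4:
            raise ValueError(
                f"fourth_peak anchor needs >= 4 peaks, found {len(peaks)}")
        return float(peaks["peak_time_s"].iloc[3])
    if anchor == "max_amplitude_peak":
        return float(peaks.loc[peaks["amplitude_mm"].idxmax(), "peak_time_s"])
    raise ValueError(f"unknown anchor: {anchor!r}")


def synchronize(truth: BreathingTrace, measured: BreathingTrace,
                anchor: str = "fourth_peak") -> AlignedPair:
    """Time-shift the measured trace so anchor peaks coincide, then
    interpolate both signals onto the overlap region of the truth grid.

    The anchor is either the fourth detected peak (a stable match point
    after the tracker's learning period) or the peak of maximum amplitude.
    """
    t_truth = _anchor_time(truth, anchor)
    t_meas = _anchor_time(measured, anchor)
    shift = t_truth - t_meas

    m_times = measured.times + shift
    lo = max(truth.times[0], m_times[0])
    hi = min(truth.times[-1], m_times[-1])
    if hi <= lo:
        raise ValueError("no overlap between traces after anchoring")
    sel = (truth.times >= lo) & (truth.times <= hi)
    grid = truth.times[sel]
    meas_on_grid = np.interp(grid, m_times, measured.displacements)
    return AlignedPair(grid, truth.displacements[sel], meas_on_grid,
                       shift_s=float(shift), anchor=anchor)


def mad(pair: AlignedPair) -> float:
    """Mean absolute deviation |truth − measured| over the common grid, mm."""
    if len(pair.times) == 0:
        raise ValueError("empty aligned pair")
    return float(np.mean(np.abs(pair.truth - pair.measured)))


def pcc(pair: AlignedPair) -> float:
    """Pearson correlation coefficient of the aligned pair, in [−1, 1]."""
    if len(pair.times) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(pair.truth) == 0 or np.ptp(pair.measured) == 0:
        raise ValueError("zero-variance input")
    return float(pearsonr(pair.truth, pair.measured)[0])


def summary_row(label: str, table: CycleTable, pair: AlignedPair) -> pd.DataFrame:
    """One report row: A ± SD, T ± SD, MAD, PCC (tracker-QA table layout)."""
    s = summarize_cycles(table)
    dev = np.abs(pair.truth - pair.measured)
    return pd.DataFrame([{
        "pattern": label,
        "A_mm": s.amplitude_mean, "A_sd_mm": s.amplitude_sd,
        "T_s": s.period_mean, "T_sd_s": s.period_sd,
        "MAD_mm": float(np.mean(dev)), "MAD_sd_mm": float(np.std(dev, ddof=1)),
        "PCC": pcc(pair),
    }])
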