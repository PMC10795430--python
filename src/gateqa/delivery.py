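"""Layer-by-layer scanned delivery onto a 1-D moving target.

Simulates pencil-beam raster scanning: spots are delivered in order, layer
by layer, at a constant particle rate; the delivery clock advances
continuously, but weight is deposited only while the beam signal is on
(gated delivery pauses at gate-off and resumes afterwards, so the full
plan weight is always delivered as long as the gate keeps opening).

Dose is scored in the target frame along the scan/motion axis: a
sub-weight w deposited at lab position s while the target sits at x(t)
adds a Gaussian of integral w and the plan's spot FWHM centred at
s − x(t). Interplay between scanning timing and target motion is exactly
what this reproduces; depth (range) structure is not modelled — layers
differ only in delivery time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .breathing import BreathingTrace
from .gating import GateSignal

__all__ = [
    "SpotPlan",
    "DeliveryTiming",
    "MotionModel",
    "GridSpec",
    "DoseProfile",
    "make_uniform_plan",
    "simulate_delivery",
    "point_dose",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SpotPlan:
    """Ordered scan layers; each layer an (n, 2) array of (position mm, weight)."""

    layers: Sequence[np.ndarray]
    fwhm: float = 10.0  # lateral spot FWHM, mm

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if len(self.layers) == 0:
            raise ValueError("plan needs at least one layer")
        self.layers = [np.asarray(l, dtype=float).reshape(-1, 2)
                       for l in self.layers]
        for l in self.layers:
            if np.any(l[:, 1] <= 0):
                raise ValueError("spot weights must be > 0")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def total_weight(self) -> float:
        return float(sum(l[:, 1].sum() for l in self.layers))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({
            "fwhm": self.fwhm,
            "layers": [l.tolist() for l in self.layers],
        }, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SpotPlan":
        d = json.loads(Path(path).read_text())
        return cls([np.array(l) for l in d["layers"]], fwhm=d["fwhm"])


def make_uniform_plan(extent: float, spacing: float, fwhm: float = 10.0,
                      n_layers: int = 1, weight: float = 1.0,
                      n_rows: int = 1) -> SpotPlan:
    """Uniform plan: spots centred on ``extent`` at ``spacing``, replicated
    over ``n_layers`` identical layers.

    ``n_rows`` serialises the orthogonal raster dimension: the scan line is
    traversed that many times per layer with weight/n_rows per pass, as a
    2-D raster visits each scan-axis position once per row. Multiple rows
    decorrelate scan position from breathing phase; with a single row each
    lateral position is visited only once per layer and the scan-position /
    breathing-phase correlation (interplay) is maximal.
    """
    if extent <= 0 or spacing <= 0:
        raise ValueError("extent and spacing must be > 0")
    if spacing > extent:
        raise ValueError("spacing must not exceed extent")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    n = int(round(extent / spacing)) + 1
    pos = np.linspace(-extent / 2.0, extent / 2.0, n)
    row = np.column_stack([pos, np.full(n, float(weight) / n_rows)])
    layer = np.vstack([row] * n_rows)
    return SpotPlan([layer.copy() for _ in range(n_layers)], fwhm=fwhm)


@dataclass(frozen=True)
class DeliveryTiming:
    """Beam time structure: constant particle rate plus dead times."""

    particle_rate: float  # weight units per second
    spot_settle: float = 0.002  # s between spots
    layer_switch: float = 2.0  # s between layers (energy change)
    dt: float = 0.001  # simulation sub-step, s

    def __post_init__(self) -> None:
        if self.particle_rate <= 0 or self.dt <= 0:
            raise ValueError("particle_rate and dt must be > 0")
        if self.spot_settle < 0 or self.layer_switch < 0:
            raise ValueError("dead times must be >= 0")

    @classmethod
    def for_layer_duration(cls, plan: SpotPlan, layer_duration: float = 1.5,
                           **kwargs) -> "DeliveryTiming":
        """Rate chosen so the heaviest layer takes ``layer_duration`` of
        beam-on time (default 1.5 s, so a multi-layer plan spans many
        breathing cycles)."""
        heaviest = max(float(l[:, 1].sum()) for l in plan.layers)
        return cls(particle_rate=heaviest / layer_duration, **kwargs)


@dataclass
class MotionModel:
    """Rigid surrogate-to-target coupling.

    The target on each axis follows the surrogate trace scaled by a
    per-axis peak-to-peak amplitude ratio (e.g. a 16 mm surrogate driving
    10/10/16 mm AP/LR/IS target motion gives ratios 0.625/0.625/1.0) and
    optionally delayed by a phase lag.
    """

    surrogate: Optional[BreathingTrace] = None
    ratios: Mapping[str, float] = field(
        default_factory=lambda: {"AP": 1.0, "LR": 1.0, "IS": 1.0})
    phase_lag: float = 0.0  # s

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios.values()):
            raise ValueError("amplitude ratios must be >= 0")

    def target_position(self, times: np.ndarray, axis: str = "IS") -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.surrogate is None:
            return np.zeros(t.shape)
        return self.ratios.get(axis, 1.0) * self.surrogate.interp(t - self.phase_lag)


@dataclass(frozen=True)
class GridSpec:
    """Uniform target-frame scoring grid. Default spacing 0.17 mm (the
    pixel pitch of a 150 dpi film scan)."""

    lo: float = -50.0
    hi: float = 50.0
    spacing: float = 25.4 / 150.0

    def positions(self) -> np.ndarray:
        n = int(np.floor((self.hi - self.lo) / self.spacing)) + 1
        return self.lo + self.spacing * np.arange(n)


@dataclass
class DoseProfile:
    """1-D dose density (weight per mm) vs target-frame position."""

    positions: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.positions.shape != self.dose.shape:
            raise ValueError("positions and dose must have equal length")
        d = np.diff(self.positions)
        if len(d) and not np.allclose(d, d[0]):
            raise ValueError("grid must be uniform")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def integral(self) -> float:
        return float(np.sum(self.dose) * self.spacing)

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"position_mm": self.positions,
                      "dose": self.dose}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DoseProfile":
        df = pd.read_csv(path)
        return cls(df["position_mm"].to_numpy(), df["dose"].to_numpy())


class _BeamClock:
    """Walks the beam on-intervals; hands out deposit segments."""

    def __init__(self, beam: Optional[GateSignal]):
        self.intervals = None if beam is None else beam.intervals
        self.k = 0

    def deposit(self, t: float, on_time: float):
        """Advance from clock time ``t`` until ``on_time`` of beam-on has
        elapsed; returns (segments, new clock time, undelivered on-time)."""
        if self.intervals is None:
            return [(t, t + on_time)], t + on_time, 0.0
        segs = []
        remaining = on_time
        while remaining > 1e-12:
            while (self.k < len(self.intervals)
                   and self.intervals[self.k][1] <= t):
                self.k += 1
            if self.k >= len(self.intervals):
                break
            a, b = self.intervals[self.k]
            start = max(t, a)
            take = min(remaining, b - start)
            if take > 0:
                segs.append((start, start + take))
                remaining -= take
            t = start + take
            if remaining > 1e-12:
                t = b
        return segs, t, remaining


def _gaussian_kernel(fwhm: float, spacing: float) -> np.ndarray:
    sigma = fwhm * FWHM_TO_SIGMA
    half = int(np.ceil(5.0 * sigma / spacing))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) * spacing / sigma) ** 2)
    return k / k.sum()


def simulate_delivery(plan: SpotPlan, motion: Optional[MotionModel],
                      beam: Optional[GateSignal], timing: DeliveryTiming,
                      grid: GridSpec = GridSpec(), axis: str = "IS",
                      start_time: float = 0.0,
                      ) -> Tuple[DoseProfile, dict]:
    """Deliver a spot plan and score the target-frame dose profile.

    ``motion=None`` is a static irradiation; ``beam=None`` is non-gated
    (always on). Returns the profile and a delivery log with per-spot
    timing, gate state and weight bookkeeping.
    """
    clock = _BeamClock(beam)
    t = float(start_time)
    if beam is not None and len(beam.intervals) == 0:
        return (DoseProfile(grid.positions(), np.zeros(grid.positions().size)),
                {"status": "no_beam", "spots": pd.DataFrame(),
                 "total_time": 0.0, "undelivered_weight": plan.total_weight})

    positions = grid.positions()
    binned = np.zeros(positions.size)
    rows = []
    undelivered = 0.0
    lost_weight = 0.0  # deposits falling outside the scoring grid

    for li, layer in enumerate(plan.layers):
        for si, (s_lab, w) in enumerate(layer):
            on_time = w / timing.particle_rate
            segs, t_new, rem = clock.deposit(t, on_time)
            undelivered += rem * timing.particle_rate
            for a, b in segs:
                n = max(int(np.ceil((b - a) / timing.dt)), 1)
                edges = np.linspace(a, b, n + 1)
                mids = 0.5 * (edges[:-1] + edges[1:])
                sub_w = np.diff(edges) * timing.particle_rate
                x_t = (motion.target_position(mids, axis)
                       if motion is not None else np.zeros(mids.size))
                centers = s_lab - x_t
                # linear binning onto the grid
                f = (centers - grid.lo) / grid.spacing
                i0 = np.floor(f).astype(int)
                frac = f - i0
                ok = (i0 >= 0) & (i0 < positions.size - 1)
                lost_weight += float(sub_w[~ok].sum())
                np.add.at(binned, i0[ok], sub_w[ok] * (1.0 - frac[ok]))
                np.add.at(binned, i0[ok] + 1, sub_w[ok] * frac[ok])
            rows.append({"layer": li, "spot": si, "position_mm": s_lab,
                         "weight": w, "t_start_s": t, "t_end_s": t_new,
                         "beam_on_time_s": on_time - rem,
                         "paused_s": (t_new - t) - (on_time - rem)})
            t = t_new + timing.spot_settle
        if li < plan.n_layers - 1:
            t += timing.layer_switch

    kernel = _gaussian_kernel(plan.fwhm, grid.spacing)
    dose = np.convolve(binned / grid.spacing, kernel, mode="same")
    status = "ok" if undelivered == 0 else "undelivered_weight"
    log = {"status": status, "spots": pd.DataFrame(rows),
           "total_time": t, "undelivered_weight": undelivered,
           "lost_weight": lost_weight, "axis": axis,
           "gated": beam is not None}
    return DoseProfile(positions, dose), log


def point_dose(profile: DoseProfile, position: float) -> float:
    """Linear interpolation of the profile at a point (the chamber analog)."""
    if not (profile.positions[0] <= position <= profile.positions[-1]):
        raise ValueError("position outside the profile grid")
    return float(np.interp(position, profile.positions, profile.dose))


def export_film_image(profile: DoseProfile, path: Union[str, Path],
                      height_px: int = 64) -> None:
    """Optional film-like 16-bit TIFF export (profile broadcast over the
    orthogonal axis); requires tifffile."""
    import tifffile

    norm = profile.dose / profile.dose.max() if profile.dose.max() > 0 else profile.dose
    img = np.tile((norm * 65535).astype(np.uint16), (height_px, 1))
    tifffile.imwrite(str(path), img)
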