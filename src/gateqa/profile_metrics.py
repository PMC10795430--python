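"""Geometric film-style metrics on 1-D dose profiles.

FWHM, field width at 90%, 80→20 lateral fall-offs, edge shifts between a
test and a reference profile at a stated dose level, and the conversion of
an edge shift into a beam latency via the waveform's maximum speed.

All relative levels are taken against the profile's plateau (the mean dose
over the central half of the above-half-maximum region) rather than the
raw maximum, so isolated noise spikes do not distort the widths. For noisy
multi-crossing profiles the outermost crossings define each width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .breathing import max_speed_cos4
from .delivery import DoseProfile

__all__ = [
    "ProfileMetrics",
    "EdgeShift",
    "plateau_level",
    "width_at",
    "falloff_80_20",
    "edge_shift",
    "latency_from_shift",
    "compute_metrics",
]


@dataclass(frozen=True)
class ProfileMetrics:
    fwhm: float
    field_width_90: float
    falloff_left: float
    falloff_right: float
    plateau: float

    def as_row(self, label: str = "") -> pd.DataFrame:
        return pd.DataFrame([{
            "profile": label,
            "FWHM_mm": self.fwhm,
            "field_size_90_mm": self.field_width_90,
            "left_falloff_80_20_mm": self.falloff_left,
            "right_falloff_80_20_mm": self.falloff_right,
            "plateau_dose": self.plateau,
        }])


@dataclass(frozen=True)
class EdgeShift:
    """Signed (test − reference) shift of the low- and high-coordinate
    level crossings, mm, at the stated level (% of plateau)."""

    low: float
    high: float
    level: float
    labels: Optional[dict] = None


def plateau_level(profile: DoseProfile) -> float:
    """Mean dose over the central 50% of the above-half-maximum region."""
    d = profile.dose
    if not np.any(d > 0):
        raise ValueError("all-zero profile")
    above = profile.positions[d >= 0.5 * d.max()]
    center = 0.5 * (above[0] + above[-1])
    span = above[-1] - above[0]
    sel = (profile.positions >= center - span / 4.0) & \
          (profile.positions <= center + span / 4.0)
    return float(d[sel].mean())


def _crossings(profile: DoseProfile, threshold: float) -> np.ndarray:
    """All linearly interpolated positions where the dose crosses threshold."""
    p, d = profile.positions, profile.dose
    s = d - threshold
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    out = [p[i] + (p[i + 1] - p[i]) * (-s[i]) / (s[i + 1] - s[i]) for i in idx]
    # grid nodes lying exactly on the threshold also count as crossings
    out.extend(p[np.nonzero(s == 0)[0]])
    return np.sort(np.asarray(out))


def width_at(profile: DoseProfile, level: float,
             plateau: Optional[float] = None) -> float:
    """Distance between the outermost crossings of level% of the plateau."""
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    ref = plateau_level(profile) if plateau is None else plateau
    cr = _crossings(profile, level / 100.0 * ref)
    if cr.size < 2:
        raise ValueError(f"profile does not cross the {level}% level twice")
    return float(cr[-1] - cr[0])


def falloff_80_20(profile: DoseProfile, side: str,
                  plateau: Optional[float] = None) -> float:
    """Width of the lateral fall-off from 80% to 20% of the plateau on
    one side ('left' or 'right'), using the outermost crossings."""
    ref = plateau_level(profile) if plateau is None else plateau
    c80 = _crossings(profile, 0.8 * ref)
    c20 = _crossings(profile, 0.2 * ref)
    if c80.size == 0 or c20.size == 0:
        raise ValueError("profile does not cross both the 80% and 20% levels")
    if side == "left":
        return float(abs(c80[0] - c20[0]))
    if side == "right":
        return float(abs(c20[-1] - c80[-1]))
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def edge_shift(test: DoseProfile, reference: DoseProfile,
               level: float = 50.0, labels: Optional[dict] = None) -> EdgeShift:
    """Per-edge signed difference (test − reference) of the outermost
    level-crossing positions; each profile normalised to its own plateau.

    ``labels`` may map 'low'/'high' to the gate transition each edge
    reflects (taken from delivery-log metadata): for a window at
    end-exhale with positive-inhale displacement, both gate transitions
    occur near the open/close threshold, which is the low-coordinate edge
    of the target-frame profile.
    """
    def _edges(p: DoseProfile):
        cr = _crossings(p, level / 100.0 * plateau_level(p))
        if cr.size < 2:
            raise ValueError(f"profile does not cross the {level}% level twice")
        return cr[0], cr[-1]

    t_lo, t_hi = _edges(test)
    r_lo, r_hi = _edges(reference)
    return EdgeShift(float(t_lo - r_lo), float(t_hi - r_hi), level, labels)


def latency_from_shift(shift_mm: float, amplitude: float, period: float) -> float:
    """Back-calculate a beam on/off delay T_d = |ΔL| / V from a 50%-edge
    shift, s.

    V is the maximum speed of the cos⁴ waveform: this is the operative
    "known velocity of the moving film" — it is the only velocity that
    converts the measured sub-millimetre shifts into the reported delay
    times consistently for both the beam-on and beam-off edges.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    return abs(shift_mm) / max_speed_cos4(amplitude, period)


def compute_metrics(profile: DoseProfile) -> ProfileMetrics:
    """All geometric metrics of one profile."""
    plat = plateau_level(profile)
    return ProfileMetrics(
        fwhm=width_at(profile, 50.0, plat),
        field_width_90=width_at(profile, 90.0, plat),
        falloff_left=falloff_80_20(profile, "left", plat),
        falloff_right=falloff_80_20(profile, "right", plat),
        plateau=plat,
    )
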