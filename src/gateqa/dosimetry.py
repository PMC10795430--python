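"""Ionization-chamber absolute dosimetry.

Absorbed dose to water from a chamber reading: the raw reading is
corrected for air density (temperature/pressure), incomplete saturation
and polarity, then multiplied by the Co-60 calibration coefficient and the
beam-quality factor k_Q. Also provides the signed dose-deviation
convention used in QA reports (positive = measurement smaller than the
planned/reference dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationConstants",
    "ChamberMeasurement",
    "corrected_reading",
    "dose_to_water",
    "dose_deviation_pct",
    "deviation_table",
]

#: standard dosimetry-protocol reference conditions
REF_TEMPERATURE_C = 20.0
REF_PRESSURE_HPA = 1013.25


@dataclass(frozen=True)
class CalibrationConstants:
    """N_D,w (Co-60) calibration coefficient, Gy per reading unit, and the
    chamber-specific beam-quality factor k_Q."""

    n_dw_co60: float = 1.0
    k_q: float = 1.0

    def __post_init__(self) -> None:
        if self.n_dw_co60 <= 0 or self.k_q <= 0:
            raise ValueError("calibration constants must be > 0")


@dataclass(frozen=True)
class ChamberMeasurement:
    """Raw chamber reading with its ambient conditions and the saturation
    and polarity correction factors."""

    reading: float
    temperature_c: float = REF_TEMPERATURE_C
    pressure_hpa: float = REF_PRESSURE_HPA
    k_s: float = 1.0
    k_pol: float = 1.0

    def __post_init__(self) -> None:
        if self.pressure_hpa <= 0:
            raise ValueError("pressure must be > 0")
        if self.k_s <= 0 or self.k_pol <= 0:
            raise ValueError("k_s and k_pol must be > 0")


def corrected_reading(meas: ChamberMeasurement,
                      ref_temperature_c: float = REF_TEMPERATURE_C,
                      ref_pressure_hpa: float = REF_PRESSURE_HPA) -> float:
    """M_corr = M · k_TP · k_s · k_pol with
    k_TP = ((273.15 + T) / (273.15 + T_ref)) · (P_ref / P)."""
    k_tp = ((273.15 + meas.temperature_c) / (273.15 + ref_temperature_c)
            ) * (ref_pressure_hpa / meas.pressure_hpa)
    return meas.reading * k_tp * meas.k_s * meas.k_pol


def dose_to_water(m_corr: float, cal: CalibrationConstants) -> float:
    """D_w = M_corr · N_D,w,Co-60 · k_Q, Gy."""
    return m_corr * cal.n_dw_co60 * cal.k_q


def dose_deviation_pct(reference: float, measured: float) -> float:
    """Signed deviation 100·(reference − measured)/reference, %.
    Positive means the measurement was smaller than the reference."""
    if reference == 0:
        raise ValueError("reference dose must be nonzero")
    return 100.0 * (reference - measured) / reference


def deviation_table(rows: dict) -> pd.DataFrame:
    """QA-report layout: mean ± SD of repeated deviations per condition.

    ``rows`` maps a condition label to a sequence of per-run deviations
    (already in %)."""
    out = []
    for label, devs in rows.items():
        d = np.asarray(list(devs), dtype=float)
        out.append({"condition": label,
                    "deviation_mean_pct": float(d.mean()),
                    "deviation_sd_pct": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                    "n": d.size})
    return pd.DataFrame(out)
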