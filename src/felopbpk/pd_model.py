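"""Pharmacodynamics: circadian baselines for diastolic blood pressure (DBP)
and heart rate (HR) with direct-effect Emax modulation by the felodipine
plasma concentration.

Baselines are multiplicative (percent-of-mean) cosine harmonics:

    DBP(t) = BP_mean · [1 + (amp24/100)·cos(2π(t−phase24)/24)
                          + (amp12/100)·cos(2π(t−phase12)/12)]
    HR(t)  = HR_mean · [1 + (amp/100)·cos(2π(t−phase)/24)]

with t the clock time in hours.  Felodipine lowers blood pressure and raises
heart rate; effects are direct (no lag, no tolerance):

    DBP(t) = baseline_bp(t) − Emax·C^h/(EC50^h + C^h)
    HR(t)  = baseline_hr(t) + Emax·C^h/(EC50^h + C^h)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CircadianBPParameters",
    "CircadianHRParameters",
    "EmaxParameters",
    "emax_effect",
    "baseline_bp",
    "baseline_hr",
    "predict_pd",
    "fit_circadian",
    "healthy_bp_parameters",
    "hypertensive_bp_parameters",
    "healthy_hr_parameters",
    "hypertensive_hr_parameters",
    "bp_emax_parameters",
    "hr_emax_parameters",
    "DEFAULT_DOSING_CLOCK_TIME_H",
]

#: Default clock time of drug administration when a protocol gives none.
DEFAULT_DOSING_CLOCK_TIME_H = 8.0


class PDError(ValueError):
    pass


@dataclass(frozen=True)
class CircadianBPParameters:
    amp24: float      # % of mean
    amp12: float      # % of mean
    phase24: float    # h
    phase12: float    # h
    bp_mean: float    # mmHg

    def __post_init__(self) -> None:
        if self.amp24 < 0 or self.amp12 < 0:
            raise PDError("circadian amplitudes must be >= 0")
        if not 40.0 < self.bp_mean < 130.0:
            raise PDError(f"bp_mean out of physiological range: {self.bp_mean}")


@dataclass(frozen=True)
class CircadianHRParameters:
    amp: float        # % of mean
    phase: float      # h
    hr_mean: float    # bpm

    def __post_init__(self) -> None:
        if self.amp < 0:
            raise PDError("circadian amplitude must be >= 0")
        if not 40.0 < self.hr_mean < 120.0:
            raise PDError(f"hr_mean out of physiological range: {self.hr_mean}")


@dataclass(frozen=True)
class EmaxParameters:
    emax: float       # mmHg or bpm
    ec50: float       # µmol/L
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.emax < 0 or self.ec50 <= 0 or self.hill <= 0:
            raise PDError("emax >= 0, ec50 > 0 and hill > 0 required")


def healthy_bp_parameters() -> CircadianBPParameters:
    return CircadianBPParameters(amp24=2.14, amp12=5.93, phase24=5.28,
                                 phase12=0.16, bp_mean=70.4)


def hypertensive_bp_parameters() -> CircadianBPParameters:
    return replace(healthy_bp_parameters(), bp_mean=91.9)


def healthy_hr_parameters() -> CircadianHRParameters:
    return CircadianHRParameters(amp=6.3, phase=11.8, hr_mean=62.2)


def hypertensive_hr_parameters() -> CircadianHRParameters:
    return replace(healthy_hr_parameters(), hr_mean=66.4)


def bp_emax_parameters() -> EmaxParameters:
    """Maximum felodipine effect on diastolic blood pressure (no hill
    coefficient: ordinary Emax)."""
    return EmaxParameters(emax=56.18, ec50=0.04, hill=1.0)


def hr_emax_parameters() -> EmaxParameters:
    """Sigmoid Emax parameters for the heart-rate increase."""
    return EmaxParameters(emax=39.71, ec50=0.05, hill=1.40)


def emax_effect(c, p: EmaxParameters):
    """Direct Emax effect, E = emax·c^h/(ec50^h + c^h); monotone in c and
    bounded by emax."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise PDError("concentration must be >= 0")
    ch = np.where(c > 0, c ** p.hill, 0.0)
    out = p.emax * ch / (p.ec50 ** p.hill + ch)
    return float(out) if out.ndim == 0 else out


def baseline_bp(t, p: CircadianBPParameters):
    """Circadian baseline diastolic blood pressure (mmHg); t is clock time in
    hours (wraps modulo 24)."""
    t = np.asarray(t, dtype=float)
    out = p.bp_mean * (
        1.0
        + p.amp24 / 100.0 * np.cos(2 * np.pi * (t - p.phase24) / 24.0)
        + p.amp12 / 100.0 * np.cos(2 * np.pi * (t - p.phase12) / 12.0)
    )
    return float(out) if out.ndim == 0 else out


def baseline_hr(t, p: CircadianHRParameters):
    """Circadian baseline heart rate (bpm); single 24-h harmonic."""
    t = np.asarray(t, dtype=float)
    out = p.hr_mean * (1.0 + p.amp / 100.0 * np.cos(2 * np.pi * (t - p.phase) / 24.0))
    return float(out) if out.ndim == 0 else out


def predict_pd(
    profile,
    bp: CircadianBPParameters,
    hr: CircadianHRParameters,
    bp_effect: EmaxParameters,
    hr_effect: EmaxParameters,
    clock_offset: float = DEFAULT_DOSING_CLOCK_TIME_H,
    compound: str = "felodipine",
) -> pd.DataFrame:
    """Effect-time series from a simulated concentration profile.

    ``clock_offset`` is the clock time (h) at simulation time zero.  Returns a
    DataFrame with columns time_min, clock_h, concentration_umol_L, dbp_mmHg,
    heart_rate_bpm.
    """
    c = np.asarray(profile.plasma_concentration(compound), dtype=float)
    t_min = np.asarray(profile.times, dtype=float)
    clock = clock_offset + t_min / 60.0
    dbp = baseline_bp(clock, bp) - emax_effect(c, bp_effect)
    hr_t = baseline_hr(clock, hr) + emax_effect(c, hr_effect)
    return pd.DataFrame({
        "time_min": t_min,
        "clock_h": clock,
        "concentration_umol_L": c,
        "dbp_mmHg": dbp,
        "heart_rate_bpm": hr_t,
    })


def fit_circadian(
    times_h: Sequence[float],
    values: Sequence[float],
    params: CircadianBPParameters | CircadianHRParameters,
    free: Sequence[str] = ("mean", "phase"),
):
    """Re-estimate circadian phase and/or mean from placebo measurements.

    Amplitudes are kept at their published values; this mirrors the per-study
    adjustment workflow where only phases and the 24-h mean are optimized.
    Returns a parameter object of the same type.
    """
    t = np.asarray(times_h, float)
    v = np.asarray(values, float)
    is_bp = isinstance(params, CircadianBPParameters)

    if is_bp:
        names = {"mean": ("bp_mean",), "phase": ("phase24", "phase12")}
    else:
        names = {"mean": ("hr_mean",), "phase": ("phase",)}
    fields = [f for key in free for f in names[key]]
    if not fields:
        raise PDError("no free circadian parameters requested")
    x0 = np.array([getattr(params, f) for f in fields])

    def residuals(x):
        p = replace(params, **dict(zip(fields, x)))
        base = baseline_bp(t, p) if is_bp else baseline_hr(t, p)
        return base - v

    res = least_squares(residuals, x0)
    return replace(params, **dict(zip(fields, res.x)))
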