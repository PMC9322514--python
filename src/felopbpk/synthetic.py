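"""Synthetic study fixtures: protocols plus noisy "observed" PK/PD series
with the statistical structure the evaluation metrics assume.

Fixtures emulate digitized clinical profiles: sparse clinical sampling grids,
multiplicative log-normal residual noise on concentrations (default CV 20%),
additive Gaussian noise on blood pressure and heart rate (default 4 mmHg /
5 bpm), and censoring below a lower limit of quantification (default
0.1 ng/mL).  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from . import ddi, pd_model
from .compound import (
    IV_INFUSION, ORAL_SOLUTION, TABLET, TABLET_ER,
    builtin_dehydrofelodipine, builtin_felodipine,
)
from .engine import DosingEvent, SimulationProtocol, TimeProfile, simulate
from .metrics import ObservedSeries
from .physiology import build_default_individual

__all__ = [
    "SCENARIOS",
    "make_study_fixture",
    "make_pd_placebo_fixture",
    "build_protocol",
    "add_concentration_noise",
    "DEFAULT_SAMPLE_TIMES_H",
    "DEFAULT_CV",
    "DEFAULT_LLOQ_NG_ML",
    "DEFAULT_SIGMA_BP",
    "DEFAULT_SIGMA_HR",
]

SCENARIOS = (
    "iv", "solution", "tablet", "tabER",
    "ddi_competitive", "ddi_mbi", "ddi_induction", "pd",
)

DEFAULT_SAMPLE_TIMES_H = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)
DEFAULT_CV = 0.20            # multiplicative log-normal PK residual CV
DEFAULT_LLOQ_NG_ML = 0.1
DEFAULT_SIGMA_BP = 4.0       # mmHg, additive
DEFAULT_SIGMA_HR = 5.0       # bpm, additive
DEFAULT_DURATION_MIN = 2880.0

# printed dose ranges the protocol layer supports
_IV_DOSE_RANGE = (1.0, 3.0)
_ORAL_DOSE_RANGE = (5.0, 40.0)

# generic perpetrator exposures for DDI fixtures: an azole-like competitive
# inhibitor, a macrolide-like mechanism-based inactivator, an
# anticonvulsant-like inducer (constant unbound exposures, µmol/L)
_DDI_PERPETRATORS = {
    "ddi_competitive": ddi.Perpetrator(
        "competitive_inhibitor",
        ddi.InteractionParameters(mechanism="competitive", ki=0.0013),
        ddi.PerpetratorExposure(constant=0.002),
    ),
    "ddi_mbi": ddi.Perpetrator(
        "mechanism_based_inhibitor",
        ddi.InteractionParameters(mechanism="mechanism_based", k_inact=0.03, K_I=10.0),
        ddi.PerpetratorExposure(constant=5.0),
    ),
    "ddi_induction": ddi.Perpetrator(
        "inducer",
        ddi.InteractionParameters(mechanism="induction", emax_ind=9.0, ec50_ind=7.0),
        ddi.PerpetratorExposure(constant=30.0),
    ),
}


class FixtureError(ValueError):
    pass


def build_protocol(
    scenario: str,
    dose: float,
    duration: float = DEFAULT_DURATION_MIN,
    output_grid: float = 5.0,
    individual=None,
    kcat_scaling: float = 1.0,
) -> SimulationProtocol:
    """Study protocol for one of the supported scenarios (dose in mg)."""
    if scenario not in SCENARIOS:
        raise FixtureError(f"unknown scenario {scenario!r}")
    lo, hi = _IV_DOSE_RANGE if scenario == "iv" else _ORAL_DOSE_RANGE
    if not lo <= dose <= hi:
        raise FixtureError(
            f"{scenario}: dose {dose} mg outside supported range [{lo}, {hi}]"
        )
    if scenario == "iv":
        event = DosingEvent("felodipine", "iv_infusion", dose,
                            formulation=IV_INFUSION)
    else:
        form = {"tablet": TABLET, "tabER": TABLET_ER}.get(scenario, ORAL_SOLUTION)
        event = DosingEvent("felodipine", "oral", dose, formulation=form)
    perps = ()
    if scenario in _DDI_PERPETRATORS:
        perps = (_DDI_PERPETRATORS[scenario],)
    return SimulationProtocol(
        individual=individual or build_default_individual(),
        parent=builtin_felodipine(),
        metabolite=builtin_dehydrofelodipine(),
        events=(event,),
        duration=duration,
        output_grid=output_grid,
        perpetrators=perps,
        kcat_scaling=kcat_scaling,
    )


def add_concentration_noise(
    values: np.ndarray, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative log-normal residual noise with coefficient of variation
    ``cv`` (the log-scale sigma is sqrt(ln(1 + cv²)), so the noise multiplier
    has unit median)."""
    if cv == 0.0:
        return np.asarray(values, float).copy()
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.asarray(values, float) * rng.lognormal(0.0, sigma, size=len(values))


def _sample_profile(
    profile: TimeProfile,
    sample_times_min: np.ndarray,
    compound: str,
) -> np.ndarray:
    return np.interp(
        sample_times_min, profile.times,
        profile.plasma_concentration(compound, units="ng_ml"),
    )


def make_study_fixture(
    scenario: str,
    dose: float,
    seed: int,
    cv: float = DEFAULT_CV,
    lloq: Optional[float] = DEFAULT_LLOQ_NG_ML,
    sample_times_h: Sequence[float] = DEFAULT_SAMPLE_TIMES_H,
    sigma_bp: float = DEFAULT_SIGMA_BP,
    sigma_hr: float = DEFAULT_SIGMA_HR,
    duration: float = DEFAULT_DURATION_MIN,
    profile: Optional[TimeProfile] = None,
) -> tuple[SimulationProtocol, list[ObservedSeries]]:
    """Simulate the true model and emit a noisy sparse 'clinical' dataset.

    Returns the protocol together with observed series: felodipine and
    dehydrofelodipine concentrations, plus DBP/HR effect series for the
    ``pd`` scenario.  Passing a precomputed ``profile`` (from the same
    protocol) skips re-simulation, e.g. for replicate noise realizations.
    """
    protocol = build_protocol(scenario, dose, duration=duration)
    if profile is None:
        profile = simulate(protocol)
    rng = np.random.default_rng(seed)
    t_sample = np.asarray(sample_times_h, float) * 60.0
    t_sample = t_sample[t_sample <= duration]

    series: list[ObservedSeries] = []
    for compound in ("felodipine", "dehydrofelodipine"):
        truth = _sample_profile(profile, t_sample, compound)
        noisy = add_concentration_noise(truth, cv, rng)
        if lloq is not None:
            below = noisy < lloq
            noisy = np.where(below, lloq, noisy)
        else:
            below = np.zeros(len(noisy), bool)
        series.append(ObservedSeries(
            times=tuple(t_sample), values=tuple(noisy),
            kind="concentration", compound=compound,
            lloq=lloq, below_lloq=tuple(bool(b) for b in below),
        ))

    if scenario == "pd":
        frame = pd_model.predict_pd(
            profile,
            pd_model.healthy_bp_parameters(), pd_model.healthy_hr_parameters(),
            pd_model.bp_emax_parameters(), pd_model.hr_emax_parameters(),
        )
        dbp = np.interp(t_sample, frame["time_min"], frame["dbp_mmHg"])
        hr = np.interp(t_sample, frame["time_min"], frame["heart_rate_bpm"])
        dbp_noisy = dbp + (rng.normal(0.0, sigma_bp, len(dbp)) if sigma_bp else 0.0)
        hr_noisy = hr + (rng.normal(0.0, sigma_hr, len(hr)) if sigma_hr else 0.0)
        series.append(ObservedSeries(tuple(t_sample), tuple(dbp_noisy),
                                     kind="dbp", compound=None))
        series.append(ObservedSeries(tuple(t_sample), tuple(hr_noisy),
                                     kind="hr", compound=None))

    return protocol, series


def make_pd_placebo_fixture(
    bp_params: Optional[pd_model.CircadianBPParameters] = None,
    hr_params: Optional[pd_model.CircadianHRParameters] = None,
    seed: int = 0,
    sigma_bp: float = DEFAULT_SIGMA_BP,
    sigma_hr: float = DEFAULT_SIGMA_HR,
    hypertensive: bool = False,
    sample_times_h: Sequence[float] = tuple(np.arange(0.0, 24.1, 2.0)),
) -> tuple[ObservedSeries, ObservedSeries]:
    """24-h placebo DBP/HR series from the circadian baselines plus additive
    Gaussian noise, supporting the per-study phase/mean re-fitting workflow."""
    if bp_params is None:
        bp_params = (pd_model.hypertensive_bp_parameters() if hypertensive
                     else pd_model.healthy_bp_parameters())
    if hr_params is None:
        hr_params = (pd_model.hypertensive_hr_parameters() if hypertensive
                     else pd_model.healthy_hr_parameters())
    rng = np.random.default_rng(seed)
    t_h = np.asarray(sample_times_h, float)
    dbp = pd_model.baseline_bp(t_h, bp_params)
    hr = pd_model.baseline_hr(t_h, hr_params)
    if sigma_bp:
        dbp = dbp + rng.normal(0.0, sigma_bp, t_h.size)
    if sigma_hr:
        hr = hr + rng.normal(0.0, sigma_hr, t_h.size)
    t_min = tuple(t_h * 60.0)
    return (
        ObservedSeries(t_min, tuple(dbp), kind="dbp", compound=None),
        ObservedSeries(t_min, tuple(hr), kind="hr", compound=None),
    )
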