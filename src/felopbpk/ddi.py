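"""CYP3A4 perturbation kinetics for drug-drug interaction simulation.

Three perpetrator mechanisms are supported:

* competitive inhibition — the victim's Michaelis constant is scaled to
  ``km_app = km × (1 + Σ I_u/Ki)`` (first-order CYP3A4 clearances are divided
  by the same factor); the enzyme pool is untouched;
* mechanism-based inactivation (MBI) — irreversible loss of active enzyme,
  ``dE/dt = k_deg·E0 − k_deg·E − k_inact·I_u/(K_I + I_u)·E``;
* induction — increased synthesis,
  ``dE/dt = k_deg·E0·(1 + Emax_ind·I_u/(EC50_ind + I_u)) − k_deg·E``.

Perpetrators are represented by unbound concentration-time forcing functions
(constant or piecewise-linear tables), optionally scaled per organ, rather
than by co-integrated PBPK systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "InteractionParameters",
    "PerpetratorExposure",
    "Perpetrator",
    "EnzymeState",
    "apparent_km",
    "enzyme_turnover_rhs",
    "mbi_steady_state",
    "induction_steady_state",
    "ddi_ratio",
    "KDEG_LIVER",
    "KDEG_GUT",
]

MECHANISMS = ("competitive", "mechanism_based", "induction")

#: CYP3A4 degradation rate constants (1/min) from literature turnover
#: half-lives: liver 36 h, gut 23 h.
KDEG_LIVER = math.log(2.0) / (36.0 * 60.0)
KDEG_GUT = math.log(2.0) / (23.0 * 60.0)


class DDIError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionParameters:
    """CYP3A4 interaction parameters; exactly the fields of the declared
    mechanism must be set."""

    mechanism: str
    ki: Optional[float] = None         # µmol/L, competitive
    k_inact: Optional[float] = None    # 1/min, MBI
    K_I: Optional[float] = None        # µmol/L, MBI
    emax_ind: Optional[float] = None   # dimensionless, induction
    ec50_ind: Optional[float] = None   # µmol/L, induction

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise DDIError(f"unknown mechanism {self.mechanism!r}")
        required = {
            "competitive": ("ki",),
            "mechanism_based": ("k_inact", "K_I"),
            "induction": ("emax_ind", "ec50_ind"),
        }[self.mechanism]
        all_fields = ("ki", "k_inact", "K_I", "emax_ind", "ec50_ind")
        for name in all_fields:
            v = getattr(self, name)
            if name in required:
                if v is None or v <= 0:
                    raise DDIError(f"{self.mechanism}: {name} must be set and > 0")
            elif v is not None:
                raise DDIError(f"{self.mechanism}: field {name} not applicable")


@dataclass(frozen=True)
class PerpetratorExposure:
    """Unbound perpetrator concentration forcing function (µmol/L).

    Either a constant or a piecewise-linear table ``(times_min, concs)``;
    ``organ_multipliers`` scales the systemic exposure per expressing organ
    (keys: 'liver' and gut segment names), e.g. to emulate high enterocyte
    exposure after oral perpetrator dosing.
    """

    constant: Optional[float] = None
    times: Optional[tuple] = None
    concs: Optional[tuple] = None
    organ_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.constant is None and (self.times is None or self.concs is None):
            raise DDIError("exposure needs a constant or a (times, concs) table")
        if self.constant is not None and self.constant < 0:
            raise DDIError("exposure must be non-negative")
        if self.times is not None:
            t = np.asarray(self.times, float)
            c = np.asarray(self.concs, float)
            if t.size != c.size or t.size < 2:
                raise DDIError("exposure table needs matching times/concs, >= 2 points")
            if np.any(np.diff(t) <= 0) or np.any(c < 0):
                raise DDIError("exposure table times must increase, concs >= 0")

    def conc(self, t: float, organ: str = "liver") -> float:
        mult = self.organ_multipliers.get(organ, 1.0)
        if self.constant is not None:
            return self.constant * mult
        return float(np.interp(t, self.times, self.concs)) * mult

    @property
    def is_constant(self) -> bool:
        return self.constant is not None

    def max_conc(self) -> float:
        if self.constant is not None:
            base = self.constant
        else:
            base = float(np.max(self.concs))
        mult = max(self.organ_multipliers.values(), default=1.0)
        return base * max(mult, 1.0)


@dataclass(frozen=True)
class Perpetrator:
    name: str
    interaction: InteractionParameters
    exposure: PerpetratorExposure


@dataclass
class EnzymeState:
    """Active CYP3A4 concentration per expressing organ (µmol/L) with its
    turnover constants; without perturbation E = E0 is a fixed point."""

    concentrations: dict[str, float]
    baseline: dict[str, float]
    k_deg: dict[str, float]

    def __post_init__(self) -> None:
        for organ, e in self.concentrations.items():
            if e < 0:
                raise DDIError(f"{organ}: enzyme concentration must be >= 0")


def apparent_km(km: float, inhibitors: Sequence[tuple[float, float]]) -> float:
    """Competitive-inhibition apparent Michaelis constant:
    km_app = km × (1 + Σ_i I_i/Ki_i)."""
    total = 0.0
    for conc, ki in inhibitors:
        if conc < 0 or ki <= 0:
            raise DDIError("inhibitor concentrations must be >= 0 and Ki > 0")
        total += conc / ki
    return km * (1.0 + total)


def enzyme_turnover_rhs(
    state: EnzymeState,
    exposure: PerpetratorExposure,
    params: InteractionParameters,
    t: float,
) -> dict[str, float]:
    """d(active enzyme)/dt per organ for a single perpetrator."""
    out: dict[str, float] = {}
    for organ, e in state.concentrations.items():
        e0 = state.baseline[organ]
        kdeg = state.k_deg[organ]
        i_u = exposure.conc(t, organ)
        if params.mechanism == "mechanism_based":
            inact = params.k_inact * i_u / (params.K_I + i_u) if i_u > 0 else 0.0
            out[organ] = kdeg * e0 - kdeg * e - inact * e
        elif params.mechanism == "induction":
            ind = 1.0 + params.emax_ind * i_u / (params.ec50_ind + i_u)
            out[organ] = kdeg * e0 * ind - kdeg * e
        else:  # competitive: enzyme pool untouched
            out[organ] = kdeg * (e0 - e)
    return out


def mbi_steady_state(
    e0: float, k_deg: float, k_inact: float, K_I: float, i_u: float
) -> float:
    """Closed-form steady state under constant exposure with MBI."""
    return e0 * k_deg / (k_deg + k_inact * i_u / (K_I + i_u))


def induction_steady_state(
    e0: float, emax_ind: float, ec50_ind: float, i_u: float
) -> float:
    """Closed-form steady state under constant exposure with induction."""
    return e0 * (1.0 + emax_ind * i_u / (ec50_ind + i_u))


def ddi_ratio(treated, control, compound: str = "felodipine") -> tuple[float, float]:
    """AUC_last and C_max ratios treated/control for the same compound, dose
    and output grid."""
    t1 = np.asarray(treated.times, float)
    t0 = np.asarray(control.times, float)
    if t1.shape != t0.shape or not np.allclose(t1, t0):
        raise DDIError("treated and control profiles must share the output grid")
    c_t = np.asarray(treated.plasma_concentration(compound), float)
    c_c = np.asarray(control.plasma_concentration(compound), float)
    auc_t = float(np.trapezoid(c_t, t1))
    auc_c = float(np.trapezoid(c_c, t0))
    if auc_c <= 0 or c_c.max() <= 0:
        raise DDIError("control profile has no exposure")
    return auc_t / auc_c, float(c_t.max() / c_c.max())
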