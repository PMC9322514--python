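"""Oral absorption: Weibull dissolution, luminal solubility limitation,
gastrointestinal transit and permeation, and the intestinal first-pass
bookkeeping (fraction absorbed, intestinal fraction metabolized).

The dissolution clock follows the dosage form: a single tablet-age variable
(time since administration) drives the Weibull hazard in every segment the
solid has reached.  Undissolved solid transits with the luminal fluid at the
segment transit rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .compound import CompoundParameters, FormulationSpec
from .physiology import GutSegmentSpec

if TYPE_CHECKING:  # pragma: no cover
    from .engine import TimeProfile

__all__ = [
    "LuminalState",
    "weibull_fraction_dissolved",
    "weibull_hazard",
    "dissolution_rate",
    "permeation_rate",
    "fraction_absorbed",
    "fraction_metabolized_intestinal",
]

# cap on the Weibull hazard (1/min) to keep the ODE right-hand side finite
# for shape < 1 at t -> 0 (not exercised by the built-in formulations)
_MAX_HAZARD = 1.0e3


class AbsorptionError(ValueError):
    pass


@dataclass
class LuminalState:
    """Per-segment luminal amounts plus cumulative absorption bookkeeping.

    All amounts in µmol; arrays ordered stomach -> colon.
    """

    undissolved: np.ndarray
    dissolved: np.ndarray
    permeated: np.ndarray   # cumulative, per segment
    fecal: float            # cumulative

    def __post_init__(self) -> None:
        for name in ("undissolved", "dissolved", "permeated"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr < -1e-9):
                raise AbsorptionError(f"negative {name} amounts")
        if self.fecal < -1e-9:
            raise AbsorptionError("negative fecal amount")

    def total(self) -> float:
        """Everything that entered the lumen and is still tracked by it."""
        return float(
            self.undissolved.sum() + self.dissolved.sum()
            + self.permeated.sum() + self.fecal
        )


def weibull_fraction_dissolved(t, t50: float, shape: float):
    """Cumulative Weibull release: 1 - exp(-ln2 · (t/t50)^shape).

    ``t50`` is the time to 50% dissolved (the "dissolution time" of the
    formulation); ``shape`` the dimensionless steepness exponent.
    """
    if t50 <= 0 or shape <= 0:
        raise AbsorptionError("Weibull t50 and shape must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise AbsorptionError("time must be >= 0")
    out = 1.0 - np.exp(-np.log(2.0) * (t / t50) ** shape)
    return float(out) if out.ndim == 0 else out


def weibull_hazard(t: float, t50: float, shape: float) -> float:
    """Instantaneous fractional dissolution rate of the remaining solid,
    w'(t) / (1 - w(t)) = ln2 · shape/t50 · (t/t50)^(shape-1)."""
    if t50 <= 0 or shape <= 0:
        raise AbsorptionError("Weibull t50 and shape must be > 0")
    if t <= 0.0:
        return 0.0 if shape >= 1.0 else _MAX_HAZARD
    h = np.log(2.0) * shape / t50 * (t / t50) ** (shape - 1.0)
    return float(min(h, _MAX_HAZARD))


def applicable_solubility_umol_l(
    formulation: FormulationSpec, compound: CompoundParameters
) -> float:
    """Saturation concentration limiting dissolution, in µmol/L.

    The formulation-specific solubility (extended-release tablets) overrides
    the compound solubility when present; it applies in all segments.
    """
    if formulation.kind == "tablet_ER" and formulation.formulation_solubility is not None:
        return compound.mg_to_umol(formulation.formulation_solubility)
    return compound.solubility_umol_l()


def dissolution_rate(
    state: LuminalState,
    formulation: FormulationSpec,
    compound: CompoundParameters,
    segment: GutSegmentSpec,
    segment_index: int,
    tablet_age: float,
) -> float:
    """Dissolution rate (µmol/min) in one segment.

    The Weibull time-derivative is rescaled to the remaining undissolved
    amount (hazard form) and clipped linearly to zero as the dissolved
    concentration approaches the applicable solubility.  Oral solutions are
    administered pre-dissolved, so their rate is identically zero.
    """
    if formulation.kind in ("iv_infusion", "oral_solution"):
        return 0.0
    solid = state.undissolved[segment_index]
    if solid <= 0.0:
        return 0.0
    hazard = weibull_hazard(tablet_age, formulation.weibull_t50, formulation.weibull_shape)
    c_sat = applicable_solubility_umol_l(formulation, compound)
    c_dissolved = state.dissolved[segment_index] / segment.lumen_volume
    sat_clip = min(max(1.0 - c_dissolved / c_sat, 0.0), 1.0)
    return hazard * solid * sat_clip


def permeation_rate(
    segment: GutSegmentSpec, dissolved_conc: float, compound: CompoundParameters
) -> float:
    """Transcellular permeation rate lumen -> gut wall (µmol/min).

    rate = permeability (cm/min) × effective surface area (cm²)
           × dissolved concentration (µmol/L) / 1000 (cm³ per L).
    """
    if dissolved_conc < 0:
        raise AbsorptionError("dissolved concentration must be >= 0")
    return (
        compound.intestinal_permeability * segment.surface_area * dissolved_conc / 1000.0
    )


def fraction_absorbed(profile: "TimeProfile", compound: str = "felodipine") -> float:
    """Cumulative fraction of the oral dose permeated from lumen into the
    gut wall at the end of the simulation."""
    dose = profile.oral_dose_umol(compound)
    if dose <= 0.0:
        warnings.warn("no oral dose administered; fraction absorbed is 0")
        return 0.0
    return float(profile.ledger(compound)["permeated"][-1] / dose)


def fraction_metabolized_intestinal(
    profile: "TimeProfile", compound: str = "felodipine"
) -> float:
    """Intestinal fraction metabolized: amount of the compound metabolized in
    all gut-wall segments expressing CYP3A4, relative to the administered
    oral dose, at the end of the simulation."""
    dose = profile.oral_dose_umol(compound)
    if dose <= 0.0:
        warnings.warn(
            "no oral dose administered (iv-only simulation); f_m,int is 0"
        )
        return 0.0
    return float(profile.ledger(compound)["gut_wall_metabolism"][-1] / dose)
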