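"""Drug-dependent parameters and tissue-to-plasma partition coefficients.

Built-in parameter sets for felodipine (parent) and dehydrofelodipine
(metabolite) carry the published model values: felodipine is eliminated
exclusively by saturable CYP3A4 metabolism (Km/kcat) plus passive glomerular
filtration; dehydrofelodipine by first-order CYP3A4-mediated and unspecific
hepatic clearances plus glomerular filtration.

Partition coefficients are computed from fractional tissue composition by
composition-based methods in the Rodgers-Rowland / Schmitt family.  The
implementations here are simplified single-equation variants of the cited
methods (no erythrocyte or extracellular-protein binding terms); they share
the structure

    Kpu = f_ew + X·f_iw + P·f_nl + (0.3·P + 0.7)·f_pl,   Kp = fu_plasma · Kpu

with P = 10^logP and X an ionization accumulation factor (1 for neutrals).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Optional

import yaml

from .physiology import OrganSpec, TissueComposition

__all__ = [
    "CompoundParameters",
    "FormulationSpec",
    "builtin_felodipine",
    "builtin_dehydrofelodipine",
    "partition_coefficient",
    "IV_INFUSION",
    "ORAL_SOLUTION",
    "TABLET",
    "TABLET_ER",
]

PARTITION_METHODS = ("rodgers_rowland", "schmitt", "charge_dependent_schmitt")
FORMULATION_KINDS = ("iv_infusion", "oral_solution", "tablet", "tablet_ER")

# pH conventions for ionization corrections
_PH_PLASMA = 7.4
_PH_INTRACELLULAR = 7.0
# membrane-affinity penalty for the ionized species (charge-dependent Schmitt)
_ION_LIPID_FACTOR = 0.1


class CompoundError(ValueError):
    pass


@dataclass(frozen=True)
class CompoundParameters:
    """Drug-dependent model parameters for one compound.

    Exactly one elimination parameterization is expected: saturable CYP3A4
    metabolism (``km_cyp3a4``/``kcat_cyp3a4``, felodipine) or first-order
    specific clearances (``cl_cyp3a4_specific``/``cl_hepatic_specific``,
    dehydrofelodipine).  Specific clearances are intrinsic first-order rate
    constants (1/min) referencing the intracellular water volume of the
    expressing organ; the CYP3A4-mediated one scales with the organ's relative
    CYP3A4 expression and is subject to DDI modulation, the unspecific hepatic
    one is liver-only and DDI-insensitive.
    """

    name: str
    MW: float                       # g/mol
    fu_plasma: float                # fraction
    logP: float
    solubility: float               # mg/L at reference pH
    solubility_ref_pH: float
    intestinal_permeability: float  # cm/min (transcellular)
    cellular_permeability: float    # cm/min
    gfr_fraction: float
    partition_method: str
    pKa_base: Optional[float] = None
    km_cyp3a4: Optional[float] = None        # µmol/L
    kcat_cyp3a4: Optional[float] = None      # 1/min
    cl_cyp3a4_specific: Optional[float] = None   # 1/min
    cl_hepatic_specific: Optional[float] = None  # 1/min

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise CompoundError(f"{self.name}: MW must be > 0")
        if not 0.0 < self.fu_plasma <= 1.0:
            raise CompoundError(f"{self.name}: fu_plasma must be in (0, 1]")
        if self.partition_method not in PARTITION_METHODS:
            raise CompoundError(
                f"{self.name}: unknown partition_method {self.partition_method!r}"
            )
        has_mm = self.km_cyp3a4 is not None or self.kcat_cyp3a4 is not None
        has_cl = (
            self.cl_cyp3a4_specific is not None
            or self.cl_hepatic_specific is not None
        )
        if has_mm and has_cl:
            raise CompoundError(
                f"{self.name}: Michaelis-Menten parameters and first-order "
                "specific clearances are mutually exclusive"
            )

    def mg_to_umol(self, mg: float) -> float:
        return mg / self.MW * 1000.0

    def umol_to_mg(self, umol: float) -> float:
        return umol * self.MW / 1000.0

    def solubility_umol_l(self) -> float:
        return self.mg_to_umol(self.solubility)

    # ---- serialization (lossless round trip) ----
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CompoundParameters":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CompoundParameters":
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))


@dataclass(frozen=True)
class FormulationSpec:
    """Dosage-form description; Weibull parameters for solid oral forms."""

    kind: str
    weibull_t50: Optional[float] = None         # min, time to 50% dissolved
    weibull_shape: Optional[float] = None
    formulation_solubility: Optional[float] = None  # mg/L, extended-release only

    def __post_init__(self) -> None:
        if self.kind not in FORMULATION_KINDS:
            raise CompoundError(f"unknown formulation kind {self.kind!r}")
        solid = self.kind in ("tablet", "tablet_ER")
        if solid and (self.weibull_t50 is None or self.weibull_shape is None):
            raise CompoundError(f"{self.kind}: Weibull t50 and shape are required")
        if not solid and (self.weibull_t50 is not None or self.weibull_shape is not None):
            raise CompoundError(f"{self.kind}: Weibull parameters not applicable")
        if self.formulation_solubility is not None and self.kind != "tablet_ER":
            raise CompoundError("formulation_solubility is tablet_ER-only")
        if solid and (self.weibull_t50 <= 0 or self.weibull_shape <= 0):
            raise CompoundError("Weibull t50 and shape must be > 0")


IV_INFUSION = FormulationSpec(kind="iv_infusion")
ORAL_SOLUTION = FormulationSpec(kind="oral_solution")
#: Conventional immediate-release tablet.
TABLET = FormulationSpec(kind="tablet", weibull_t50=54.86, weibull_shape=1.32)
#: Extended-release tablet with the formulation-specific (reduced) solubility
#: estimated as a surrogate for diminished distal absorption.
TABLET_ER = FormulationSpec(
    kind="tablet_ER", weibull_t50=173.04, weibull_shape=1.30,
    formulation_solubility=0.89,
)


def builtin_felodipine() -> CompoundParameters:
    """Felodipine parent-drug parameter set."""
    return CompoundParameters(
        name="felodipine",
        MW=384.25,
        fu_plasma=0.0036,          # 0.36% bound fraction unbound
        logP=4.36,
        solubility=7.15,
        solubility_ref_pH=6.5,
        intestinal_permeability=2.76e-4,
        cellular_permeability=0.42,
        gfr_fraction=1.0,
        partition_method="rodgers_rowland",
        km_cyp3a4=2.81,
        kcat_cyp3a4=250.44,
    )


def builtin_dehydrofelodipine() -> CompoundParameters:
    """Dehydrofelodipine metabolite parameter set."""
    return CompoundParameters(
        name="dehydrofelodipine",
        MW=382.24,
        fu_plasma=0.0068,
        logP=3.32,
        solubility=2.93,
        solubility_ref_pH=7.0,
        intestinal_permeability=1.38e-4,
        cellular_permeability=0.04,
        gfr_fraction=1.0,
        partition_method="schmitt",
        pKa_base=4.06,
        cl_cyp3a4_specific=35.74,
        cl_hepatic_specific=2.76,
    )


def _base_ionization_factor(pKa: float, ph_cell: float, ph_plasma: float) -> float:
    """Accumulation factor for a monoprotic base between two pH values."""
    return (1.0 + 10.0 ** (pKa - ph_cell)) / (1.0 + 10.0 ** (pKa - ph_plasma))


def _neutral_fraction_base(pKa: float, ph: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (pKa - ph))


def partition_coefficient(
    compound: CompoundParameters,
    organ: OrganSpec | TissueComposition,
) -> float:
    """Tissue-to-plasma partition coefficient Kp (total concentrations).

    Dispatches on ``compound.partition_method``.  Blood pools (plasma-like
    composition with negligible lipid) come out near fu-scaled unity; the
    engine pins them to exactly 1 since they *are* the plasma reference.
    """
    comp = organ.composition if isinstance(organ, OrganSpec) else organ
    P = 10.0 ** compound.logP
    f_w, f_nl, f_pl = comp.f_water, comp.f_neutral_lipid, comp.f_phospholipid
    method = compound.partition_method

    if method == "rodgers_rowland":
        x = 1.0
        if compound.pKa_base is not None:
            x = _base_ionization_factor(compound.pKa_base, _PH_INTRACELLULAR, _PH_PLASMA)
        kpu = 0.35 * f_w + 0.65 * f_w * x + P * f_nl + (0.3 * P + 0.7) * f_pl
    elif method == "schmitt":
        kpu = f_w + P * f_nl + (0.3 * P + 0.7) * f_pl
    elif method == "charge_dependent_schmitt":
        if compound.pKa_base is None:
            raise CompoundError(
                f"{compound.name}: charge-dependent Schmitt requires pKa_base"
            )
        fn = _neutral_fraction_base(compound.pKa_base, _PH_INTRACELLULAR)
        x = _base_ionization_factor(compound.pKa_base, _PH_INTRACELLULAR, _PH_PLASMA)
        lipid_scale = fn + (1.0 - fn) * _ION_LIPID_FACTOR
        kpu = f_w * x + lipid_scale * (P * f_nl + (0.3 * P + 0.7) * f_pl)
    else:  # pragma: no cover - guarded in __post_init__
        raise CompoundError(f"unknown partition method {method!r}")

    kp = compound.fu_plasma * kpu
    if not kp > 0:
        raise CompoundError(f"non-positive Kp computed for {compound.name}")
    return kp
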