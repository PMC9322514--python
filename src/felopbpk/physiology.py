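"""Virtual-individual physiology: organ network, blood flows, gut segmentation,
CYP3A4 expression and glomerular filtration.

The organ set is deliberately reduced relative to full platform anatomies:
lung, liver, kidney, a seven-segment gut (lumen + wall), muscle, adipose,
skin, bone, brain, heart, spleen+pancreas (draining to the portal vein),
a lumped "rest" compartment, and arterial/venous blood pools.  Distribution
is perfusion-limited (well-stirred) per organ.

Units: volumes L, blood flows L/min, GFR mL/min, enzyme concentrations
µmol/L, surface areas cm², transit rates 1/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "TissueComposition",
    "OrganSpec",
    "GutSegmentSpec",
    "VirtualIndividual",
    "build_default_individual",
    "renal_filtration_clearance",
    "SYSTEMIC_ORGANS",
    "GUT_SEGMENTS",
    "CYP3A4_REFERENCE_CONC_UM",
    "GUT_CYP3A4_EXPRESSION_SCALE",
]


class PhysiologyError(ValueError):
    """Raised for non-physiological demographics or malformed physiology."""


@dataclass(frozen=True)
class TissueComposition:
    """Fractional tissue composition used by partition-coefficient methods."""

    f_water: float
    f_neutral_lipid: float
    f_phospholipid: float

    def __post_init__(self) -> None:
        for name in ("f_water", "f_neutral_lipid", "f_phospholipid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhysiologyError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class OrganSpec:
    name: str
    volume: float            # L
    blood_flow: float        # L/min (arterial inflow; for lung: cardiac output)
    composition: TissueComposition
    cyp3a4_rel_expression: float = 0.0  # fraction of the liver reference conc

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise PhysiologyError(f"organ {self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise PhysiologyError(f"organ {self.name}: blood_flow must be >= 0")
        if self.cyp3a4_rel_expression < 0:
            raise PhysiologyError(
                f"organ {self.name}: cyp3a4_rel_expression must be >= 0"
            )


@dataclass(frozen=True)
class GutSegmentSpec:
    """One gastrointestinal segment: a luminal transit compartment plus the
    perfused mucosal wall it feeds by transcellular permeation."""

    name: str
    lumen_volume: float          # L
    transit_rate: float          # 1/min (first-order outflow to next segment)
    pH: float
    surface_area: float          # cm², effective absorptive area
    wall_volume: float           # L (mucosal tissue)
    wall_blood_flow: float       # L/min (mucosal perfusion, drains to portal vein)
    cyp3a4_rel_expression: float  # fraction of liver reference conc

    def __post_init__(self) -> None:
        if self.transit_rate <= 0:
            raise PhysiologyError(f"segment {self.name}: transit_rate must be > 0")
        if self.lumen_volume <= 0 or self.wall_volume <= 0:
            raise PhysiologyError(f"segment {self.name}: volumes must be > 0")
        if self.surface_area < 0 or self.wall_blood_flow < 0:
            raise PhysiologyError(f"segment {self.name}: negative area or flow")
        if self.cyp3a4_rel_expression < 0:
            raise PhysiologyError(f"segment {self.name}: negative CYP3A4 expression")


@dataclass(frozen=True)
class VirtualIndividual:
    age: float               # years
    sex: str
    weight: float            # kg
    height: float            # cm
    GFR: float               # mL/min
    hematocrit: float
    cyp3a4_reference_concentration: float  # µmol/L in liver tissue
    organs: dict[str, OrganSpec]
    gut: tuple[GutSegmentSpec, ...]
    cardiac_output: float    # L/min

    def __post_init__(self) -> None:
        if self.GFR <= 0:
            raise PhysiologyError("GFR must be > 0")
        systemic = sum(o.blood_flow for n, o in self.organs.items() if n != "lung")
        systemic += sum(s.wall_blood_flow for s in self.gut)
        if abs(systemic - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise PhysiologyError(
                "sum of systemic organ flows does not match cardiac output: "
                f"{systemic:.4f} vs {self.cardiac_output:.4f} L/min"
            )

    @property
    def gut_by_name(self) -> dict[str, GutSegmentSpec]:
        return {s.name: s for s in self.gut}

    @property
    def portal_flow(self) -> float:
        """Portal-vein flow: gut mucosa plus spleen+pancreas drainage."""
        return sum(s.wall_blood_flow for s in self.gut) + self.organs["spleen"].blood_flow

    @property
    def liver_total_flow(self) -> float:
        return self.portal_flow + self.organs["liver"].blood_flow


# --------------------------------------------------------------------------
# Reference physiology for the default 30-year-old, 73-kg, 176-cm European
# male.  Volumes and flows compiled from standard human physiology tables
# (ICRP-type reference man); tissue compositions from the Rodgers/Poulin
# partition-method literature.  Volumes scale linearly with body weight,
# flows with weight^0.75, GFR with body surface area.
# --------------------------------------------------------------------------

REFERENCE_WEIGHT_KG = 73.0
REFERENCE_HEIGHT_CM = 176.0
REFERENCE_GFR_ML_MIN = 120.0
REFERENCE_HEMATOCRIT = 0.45

#: Liver CYP3A4 reference concentration (µmol per L liver tissue).
CYP3A4_REFERENCE_CONC_UM = 4.32

#: Single calibration constant for intestinal CYP3A4: the duodenal mucosal
#: CYP3A4 concentration as a fraction of the hepatic reference.  The distal
#: profile below is fixed; this scale was calibrated once so that the model
#: reproduces the reported intestinal first-pass extraction of felodipine
#: (fraction of dose metabolized in the gut wall ~53% for an oral solution).
GUT_CYP3A4_EXPRESSION_SCALE = 1.0

# name: (volume L, blood flow L/min, (f_water, f_neutral_lipid, f_phospholipid))
_ORGAN_TABLE: dict[str, tuple[float, float, tuple[float, float, float]]] = {
    "lung":    (0.50, 0.0,  (0.79, 0.022, 0.0128)),   # flow set to CO at build time
    "liver":   (1.80, 0.45, (0.74, 0.035, 0.0252)),   # flow = hepatic artery only
    "kidney":  (0.31, 1.10, (0.78, 0.012, 0.0242)),
    "muscle":  (29.0, 0.75, (0.76, 0.022, 0.0072)),
    "adipose": (14.5, 0.26, (0.18, 0.790, 0.0020)),
    "skin":    (3.30, 0.30, (0.65, 0.028, 0.0044)),
    "bone":    (8.50, 0.25, (0.44, 0.074, 0.0011)),
    "brain":   (1.45, 0.70, (0.77, 0.051, 0.0565)),
    "heart":   (0.33, 0.24, (0.76, 0.014, 0.0111)),
    "spleen":  (0.30, 0.35, (0.78, 0.012, 0.0136)),   # spleen + pancreas, to portal
    "rest":    (4.50, 0.35, (0.72, 0.040, 0.0100)),
    "arterial": (1.50, 0.0, (0.945, 0.0033, 0.00225)),
    "venous":  (3.30, 0.0,  (0.945, 0.0033, 0.00225)),
}

GUT_SEGMENTS = (
    "stomach",
    "duodenum",
    "upper_jejunum",
    "lower_jejunum",
    "ileum",
    "caecum",
    "colon",
)

# name: (lumen L, transit 1/min, pH, surface cm², wall L, wall flow L/min, CYP3A4 rel)
_GUT_TABLE: dict[str, tuple[float, float, float, float, float, float, float]] = {
    # stomach: fasted emptying half-time 15 min, no absorption, no CYP3A4
    "stomach":       (0.25, math.log(2) / 15.0, 2.0, 0.0,    0.15, 0.06, 0.00),
    "duodenum":      (0.04, 1 / 10.0, 6.0, 1.2e4, 0.06, 0.06, 1.00),
    "upper_jejunum": (0.08, 1 / 60.0, 6.2, 3.0e4, 0.11, 0.14, 0.90),
    "lower_jejunum": (0.08, 1 / 60.0, 6.6, 3.0e4, 0.11, 0.14, 0.60),
    "ileum":         (0.08, 1 / 70.0, 7.4, 2.5e4, 0.16, 0.14, 0.25),
    "caecum":        (0.05, 1 / 240.0, 6.4, 1.5e3, 0.05, 0.04, 0.05),
    "colon":         (0.10, 1 / 840.0, 7.0, 3.5e3, 0.16, 0.07, 0.03),
}

# composition of gut mucosal wall
_GUT_WALL_COMPOSITION = (0.77, 0.049, 0.0163)

SYSTEMIC_ORGANS = (
    "liver", "kidney", "muscle", "adipose", "skin",
    "bone", "brain", "heart", "spleen", "rest",
)


def _body_surface_area_m2(weight: float, height: float) -> float:
    """Du Bois body surface area."""
    return 0.007184 * weight**0.425 * height**0.725


def build_default_individual(
    age: float = 30.0,
    sex: str = "male",
    weight: float = REFERENCE_WEIGHT_KG,
    height: float = REFERENCE_HEIGHT_CM,
    cyp3a4_reference_concentration: float = CYP3A4_REFERENCE_CONC_UM,
    gut_cyp3a4_scale: float = GUT_CYP3A4_EXPRESSION_SCALE,
) -> VirtualIndividual:
    """Construct a fully populated virtual individual.

    Called with no arguments this returns the default 30-year-old European
    male.  Organ volumes scale linearly with body weight, blood flows with
    weight^0.75, and GFR with body surface area.
    """
    if not 18.0 <= age <= 100.0:
        raise PhysiologyError(f"age must be in [18, 100] years, got {age}")
    if sex not in ("male", "female"):
        raise PhysiologyError(f"sex must be 'male' or 'female', got {sex!r}")
    if not 30.0 <= weight <= 250.0:
        raise PhysiologyError(f"weight must be physiological (30-250 kg), got {weight}")
    if not 120.0 <= height <= 230.0:
        raise PhysiologyError(f"height must be physiological (120-230 cm), got {height}")

    v_scale = weight / REFERENCE_WEIGHT_KG
    q_scale = (weight / REFERENCE_WEIGHT_KG) ** 0.75

    organs: dict[str, OrganSpec] = {}
    for name, (vol, flow, comp) in _ORGAN_TABLE.items():
        organs[name] = OrganSpec(
            name=name,
            volume=vol * v_scale,
            blood_flow=flow * q_scale,
            composition=TissueComposition(*comp),
            cyp3a4_rel_expression=1.0 if name == "liver" else 0.0,
        )

    gut = tuple(
        GutSegmentSpec(
            name=name,
            lumen_volume=lumen * v_scale,
            transit_rate=kt,
            pH=ph,
            surface_area=sa * v_scale ** (2.0 / 3.0),
            wall_volume=wall * v_scale,
            wall_blood_flow=q_wall * q_scale,
            cyp3a4_rel_expression=rel * gut_cyp3a4_scale,
        )
        for name, (lumen, kt, ph, sa, wall, q_wall, rel) in _GUT_TABLE.items()
    )

    cardiac_output = (
        sum(organs[n].blood_flow for n in SYSTEMIC_ORGANS)
        + sum(s.wall_blood_flow for s in gut)
    )
    organs["lung"] = replace(organs["lung"], blood_flow=cardiac_output)

    bsa = _body_surface_area_m2(weight, height)
    bsa_ref = _body_surface_area_m2(REFERENCE_WEIGHT_KG, REFERENCE_HEIGHT_CM)
    gfr = REFERENCE_GFR_ML_MIN * bsa / bsa_ref

    return VirtualIndividual(
        age=age,
        sex=sex,
        weight=weight,
        height=height,
        GFR=gfr,
        hematocrit=REFERENCE_HEMATOCRIT,
        cyp3a4_reference_concentration=cyp3a4_reference_concentration,
        organs=organs,
        gut=gut,
        cardiac_output=cardiac_output,
    )


def renal_filtration_clearance(
    individual: VirtualIndividual, fu_plasma: float, gfr_fraction: float = 1.0
) -> float:
    """Passive glomerular filtration clearance in L/min.

    CL_renal = gfr_fraction × GFR × fu_plasma, i.e. the unbound fraction of
    drug passively filtered into the urine.
    """
    if not 0.0 <= fu_plasma <= 1.0:
        raise PhysiologyError(f"fu_plasma must be in [0, 1], got {fu_plasma}")
    if gfr_fraction < 0:
        raise PhysiologyError(f"gfr_fraction must be >= 0, got {gfr_fraction}")
    return gfr_fraction * individual.GFR * fu_plasma / 1000.0
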