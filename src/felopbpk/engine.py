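"""Whole-body parent-metabolite PBPK ODE system.

The coupled system tracks, per compound, amounts (µmol) in seven gut-lumen
segments (dissolved + undissolved solid), seven perfused gut-wall segments,
thirteen perfusion-limited organ/blood compartments, and cumulative ledgers
(urinary excretion, gut-wall metabolism per segment, hepatic CYP3A4 and
unspecific metabolism, permeation per segment, fecal loss, and venous-outflow
integrals used for availability decomposition).  Every µmol of felodipine
metabolized by CYP3A4 appears as dehydrofelodipine formed in the same organ.

Internal units: time min, amounts µmol, concentrations µmol/L.  ng/mL views
are computed via the molecular weight at the I/O boundary only.

Metabolism is driven by the unbound intracellular concentration
``c_u = fu_plasma · C_tissue / Kp`` (well-stirred equilibrium).  Integration
uses a stiff BDF solver with an analytic Jacobian sparsity pattern and
restarts at every dosing-event boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from . import absorption, ddi
from .compound import CompoundParameters, FormulationSpec, partition_coefficient
from .physiology import (
    _GUT_WALL_COMPOSITION,
    TissueComposition,
    VirtualIndividual,
    renal_filtration_clearance,
)

__all__ = [
    "DosingEvent",
    "SimulationProtocol",
    "TimeProfile",
    "simulate",
    "bioavailability",
    "michaelis_menten_rate",
    "sequential_availabilities",
    "SolverError",
    "RTOL",
    "ATOL",
    "DEFAULT_INFUSION_DURATION",
    "INTRACELLULAR_FRACTION",
]

# solver configuration
RTOL = 1e-8
ATOL = 1e-10          # µmol
DEFAULT_INFUSION_DURATION = 10.0  # min
#: fraction of organ volume treated as intracellular water, the reference
#: volume of first-order "specific" clearances
INTRACELLULAR_FRACTION = 0.6

N_SEG = 7
ORGAN_ORDER = (
    "lung", "arterial", "venous", "liver", "kidney", "muscle", "adipose",
    "skin", "bone", "brain", "heart", "spleen", "rest",
)
# organs fed from the arterial pool and draining directly to the venous pool
_DIRECT_ORGANS = ("kidney", "muscle", "adipose", "skin", "bone", "brain", "heart", "rest")

# per-compound state-block layout
_LUMEN_D = slice(0, 7)
_LUMEN_S = slice(7, 14)
_WALL = slice(14, 21)
_ORGANS = slice(21, 34)
_URINE = 34
_GUT_MET = slice(35, 42)
_HEP_CYP = 42
_HEP_UNSPEC = 43
_PERM = slice(44, 51)
_FECAL = 51
_WALL_OUT = slice(52, 59)
_LIVER_OUT = 59
_BLOCK = 60

_ORG_IDX = {name: i for i, name in enumerate(ORGAN_ORDER)}


class SolverError(RuntimeError):
    """ODE integration failure, carrying the failure time and state."""

    def __init__(self, message: str, t: float, y: np.ndarray):
        super().__init__(f"{message} (t = {t:.3f} min)")
        self.t = t
        self.y = y


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class DosingEvent:
    compound: str
    route: str                      # 'iv_infusion' or 'oral'
    dose: float                     # mg
    start_time: float = 0.0         # min
    infusion_duration: Optional[float] = None  # min, iv only
    formulation: FormulationSpec = None

    def __post_init__(self) -> None:
        if self.route not in ("iv_infusion", "oral"):
            raise ProtocolError(f"unknown route {self.route!r}")
        if self.dose <= 0:
            raise ProtocolError("dose must be > 0")
        if self.start_time < 0:
            raise ProtocolError("start_time must be >= 0")
        if self.route == "iv_infusion":
            dur = self.infusion_duration
            if dur is None:
                object.__setattr__(self, "infusion_duration", DEFAULT_INFUSION_DURATION)
            elif dur <= 0:
                raise ProtocolError("infusion_duration must be > 0")
            if self.formulation is None:
                from .compound import IV_INFUSION
                object.__setattr__(self, "formulation", IV_INFUSION)
        else:
            if self.formulation is None or self.formulation.kind == "iv_infusion":
                raise ProtocolError("oral events need an oral formulation")


@dataclass(frozen=True)
class SimulationProtocol:
    """One unit of simulation work: individual + compounds + dosing events.

    The parent and metabolite are linked 1:1 molar through the CYP3A4
    pathway.  ``kcat_scaling`` scales the parent CYP3A4 kcat (e.g. 0.68 for
    the hypertensive-population workflow).
    """

    individual: VirtualIndividual
    parent: CompoundParameters
    metabolite: CompoundParameters
    events: tuple[DosingEvent, ...]
    duration: float                  # min
    output_grid: float = 5.0         # min
    perpetrators: tuple[ddi.Perpetrator, ...] = ()
    kcat_scaling: float = 1.0
    induction_at_steady_state: bool = True

    def __post_init__(self) -> None:
        if not self.events:
            raise ProtocolError("protocol needs at least one dosing event")
        events = tuple(sorted(self.events, key=lambda e: e.start_time))
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "perpetrators", tuple(self.perpetrators))
        last = max(
            e.start_time + (e.infusion_duration or 0.0) for e in self.events
        )
        if self.duration <= last:
            raise ProtocolError("duration must cover all dosing events")
        if self.kcat_scaling <= 0:
            raise ProtocolError("kcat_scaling must be > 0")
        names = {self.parent.name, self.metabolite.name}
        for e in self.events:
            if e.compound not in names:
                raise ProtocolError(f"event compound {e.compound!r} not in protocol")


def michaelis_menten_rate(
    c_unbound: float, enzyme_conc: float, kcat: float, km: float
) -> float:
    """Saturable metabolic rate density (µmol/L/min):
    kcat × E × c_u / (km + c_u)."""
    if c_unbound < 0 or enzyme_conc < 0 or kcat < 0 or km < 0:
        raise ValueError("Michaelis-Menten inputs must be >= 0")
    if c_unbound == 0.0:
        return 0.0
    return kcat * enzyme_conc * c_unbound / (km + c_unbound)


# ---------------------------------------------------------------------------
# model context: everything precomputed from the protocol
# ---------------------------------------------------------------------------


class _Context:
    def __init__(self, protocol: SimulationProtocol):
        self.protocol = protocol
        ind = protocol.individual
        self.compounds = (protocol.parent, protocol.metabolite)
        self.n_compounds = 2

        # organ geometry / flows
        self.v_org = np.array([ind.organs[n].volume for n in ORGAN_ORDER])
        self.q_org = np.array([ind.organs[n].blood_flow for n in ORGAN_ORDER])
        self.co = ind.cardiac_output
        self.direct_idx = np.array([_ORG_IDX[n] for n in _DIRECT_ORGANS])
        self.i_lung = _ORG_IDX["lung"]
        self.i_art = _ORG_IDX["arterial"]
        self.i_ven = _ORG_IDX["venous"]
        self.i_liv = _ORG_IDX["liver"]
        self.i_spl = _ORG_IDX["spleen"]

        # gut geometry
        gut = ind.gut
        self.seg_names = tuple(s.name for s in gut)
        self.v_lumen = np.array([s.lumen_volume for s in gut])
        self.kt = np.array([s.transit_rate for s in gut])
        self.sa = np.array([s.surface_area for s in gut])
        self.v_wall = np.array([s.wall_volume for s in gut])
        self.q_wall = np.array([s.wall_blood_flow for s in gut])
        self.rel_expr_gut = np.array([s.cyp3a4_rel_expression for s in gut])

        self.q_liver_total = ind.liver_total_flow
        self.q_ha = ind.organs["liver"].blood_flow
        self.q_spleen = ind.organs["spleen"].blood_flow

        # partition coefficients (blood pools are the plasma reference: Kp = 1)
        self.kp_org = np.ones((2, len(ORGAN_ORDER)))
        self.kp_wall = np.ones(2)
        for c, cmp_ in enumerate(self.compounds):
            for j, name in enumerate(ORGAN_ORDER):
                if name in ("arterial", "venous"):
                    continue
                self.kp_org[c, j] = partition_coefficient(cmp_, ind.organs[name])
            self.kp_wall[c] = partition_coefficient(
                cmp_, TissueComposition(*_GUT_WALL_COMPOSITION)
            )

        self.fu = np.array([c.fu_plasma for c in self.compounds])
        self.cl_renal = np.array(
            [renal_filtration_clearance(ind, c.fu_plasma, c.gfr_fraction)
             for c in self.compounds]
        )
        self.psa = np.array(
            [c.intestinal_permeability for c in self.compounds]
        )[:, None] * self.sa[None, :] / 1000.0   # L/min per compound/segment

        # CYP3A4 enzyme pools
        e_ref = ind.cyp3a4_reference_concentration
        self.e0_liver = e_ref
        self.e0_gut = e_ref * self.rel_expr_gut
        self.enzyme_organs = ("liver",) + self.seg_names
        self.kdeg = np.array([ddi.KDEG_LIVER] + [ddi.KDEG_GUT] * N_SEG)
        self.e0_vec = np.concatenate(([self.e0_liver], self.e0_gut))

        # parent Michaelis-Menten
        p = protocol.parent
        if p.kcat_cyp3a4 is None or p.km_cyp3a4 is None:
            raise ProtocolError("parent compound must carry CYP3A4 Km/kcat")
        self.kcat = p.kcat_cyp3a4 * protocol.kcat_scaling
        self.km = p.km_cyp3a4

        # metabolite first-order specific clearances, referencing the
        # intracellular water volume of the expressing organ
        m = protocol.metabolite
        self.v_cell_liver = INTRACELLULAR_FRACTION * ind.organs["liver"].volume
        self.v_cell_wall = INTRACELLULAR_FRACTION * self.v_wall
        self.cl_cyp_m = m.cl_cyp3a4_specific or 0.0
        self.cl_hep_m = m.cl_hepatic_specific or 0.0
        self.rel_expr_liver = 1.0

        # DDI bookkeeping
        self.perps = protocol.perpetrators
        self.dynamic_enzyme = any(
            perp.interaction.mechanism in ("mechanism_based", "induction")
            and perp.exposure.max_conc() > 0.0
            for perp in self.perps
        )
        self.all_const_exposure = all(p.exposure.is_constant for p in self.perps)
        self._static_exposure = self._exposure_terms(0.0) if self.all_const_exposure else None

        self.n_state = 2 * _BLOCK + (1 + N_SEG if self.dynamic_enzyme else 0)
        self.enzyme_slice = slice(2 * _BLOCK, self.n_state)

        # oral dose bookkeeping (per compound)
        self.oral_dose_umol = np.zeros(2)
        self.compound_index = {c.name: i for i, c in enumerate(self.compounds)}
        self.current_oral: list[Optional[tuple[float, FormulationSpec]]] = [None, None]
        for e in protocol.events:
            if e.route == "oral":
                ci = self.compound_index[e.compound]
                self.oral_dose_umol[ci] += self.compounds[ci].mg_to_umol(e.dose)

    # -- perpetrator forcing terms ------------------------------------------
    def _exposure_terms(self, t: float):
        """(competitive I/Ki sum, MBI inactivation hazard, induction factor)
        per expressing organ (liver + 7 gut segments)."""
        n = 1 + N_SEG
        comp = np.zeros(n)
        mbi = np.zeros(n)
        ind_f = np.ones(n)
        for perp in self.perps:
            pars = perp.interaction
            for o, organ in enumerate(self.enzyme_organs):
                i_u = perp.exposure.conc(t, organ)
                if i_u <= 0.0:
                    continue
                if pars.mechanism == "competitive":
                    comp[o] += i_u / pars.ki
                elif pars.mechanism == "mechanism_based":
                    mbi[o] += pars.k_inact * i_u / (pars.K_I + i_u)
                else:
                    ind_f[o] += pars.emax_ind * i_u / (pars.ec50_ind + i_u)
        return comp, mbi, ind_f

    def exposure_terms(self, t: float):
        if self._static_exposure is not None:
            return self._static_exposure
        return self._exposure_terms(t)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def _rhs(t, y, ctx: _Context, infusion: np.ndarray):
    dy = np.zeros_like(y)
    comp_sum, mbi_haz, ind_f = ctx.exposure_terms(t)

    # active enzyme concentrations
    if ctx.dynamic_enzyme:
        e_vec = y[ctx.enzyme_slice]
        dy[ctx.enzyme_slice] = (
            ctx.kdeg * ctx.e0_vec * ind_f - ctx.kdeg * e_vec - mbi_haz * e_vec
        )
    else:
        e_vec = ctx.e0_vec
    e_liver, e_gut = e_vec[0], e_vec[1:]
    km_app_liver = ctx.km * (1.0 + comp_sum[0])
    km_app_gut = ctx.km * (1.0 + comp_sum[1:])

    parent_gut_met = None
    parent_liver_met = 0.0

    for c in range(2):
        b = c * _BLOCK
        cmp_ = ctx.compounds[c]
        a_d = y[b + _LUMEN_D.start: b + _LUMEN_D.stop]
        a_s = y[b + _LUMEN_S.start: b + _LUMEN_S.stop]
        a_w = y[b + _WALL.start: b + _WALL.stop]
        a_o = y[b + _ORGANS.start: b + _ORGANS.stop]

        c_org = a_o / ctx.v_org
        c_art = c_org[ctx.i_art]
        c_ven = c_org[ctx.i_ven]
        c_out = c_org / ctx.kp_org[c]          # venous-equilibrium outflow conc
        c_wall = a_w / ctx.v_wall
        c_wall_out = c_wall / ctx.kp_wall[c]

        # ---- gut lumen ----
        c_lumen = a_d / ctx.v_lumen
        perm = ctx.psa[c] * c_lumen            # µmol/min, lumen -> wall
        diss = np.zeros(N_SEG)
        oral = ctx.current_oral[c]
        if oral is not None and a_s.sum() > 0.0:
            t_dose, form = oral
            if form.kind in ("tablet", "tablet_ER"):
                hazard = absorption.weibull_hazard(
                    t - t_dose, form.weibull_t50, form.weibull_shape
                )
                if hazard > 0.0:
                    c_sat = absorption.applicable_solubility_umol_l(form, cmp_)
                    sat = np.clip(1.0 - c_lumen / c_sat, 0.0, 1.0)
                    diss = hazard * a_s * sat

        d_d = np.zeros(N_SEG)
        d_s = np.zeros(N_SEG)
        trans_d = ctx.kt * a_d
        trans_s = ctx.kt * a_s
        d_d += diss - trans_d - perm
        d_s += -diss - trans_s
        d_d[1:] += trans_d[:-1]
        d_s[1:] += trans_s[:-1]
        dy[b + _FECAL] = trans_d[-1] + trans_s[-1]

        # ---- metabolism ----
        cu_wall = ctx.fu[c] * c_wall_out
        cu_liver = ctx.fu[c] * c_out[ctx.i_liv]
        if c == 0:  # parent: saturable CYP3A4
            met_wall = (
                ctx.kcat * e_gut * cu_wall / (km_app_gut + cu_wall) * ctx.v_wall
            )
            met_liver = ctx.kcat * e_liver * cu_liver / (km_app_liver + cu_liver) \
                * ctx.v_org[ctx.i_liv]
            parent_gut_met = met_wall
            parent_liver_met = met_liver
            met_liver_unspec = 0.0
        else:       # metabolite: first-order specific clearances
            ddi_scale_gut = np.divide(
                e_gut, ctx.e0_gut, out=np.ones(N_SEG), where=ctx.e0_gut > 0
            ) / (1.0 + comp_sum[1:])
            ddi_scale_liv = (e_liver / ctx.e0_liver) / (1.0 + comp_sum[0])
            met_wall = (
                ctx.cl_cyp_m * ctx.rel_expr_gut * ddi_scale_gut
                * ctx.v_cell_wall * cu_wall
            )
            met_liver = (
                ctx.cl_cyp_m * ctx.rel_expr_liver * ddi_scale_liv
                * ctx.v_cell_liver * cu_liver
            )
            met_liver_unspec = ctx.cl_hep_m * ctx.v_cell_liver * cu_liver

        # ---- gut wall ----
        wall_out = ctx.q_wall * c_wall_out
        d_w = ctx.q_wall * c_art - wall_out + perm - met_wall
        if c == 1:
            d_w = d_w + parent_gut_met

        # ---- organs ----
        d_o = np.zeros(len(ORGAN_ORDER))
        # directly drained organs
        qi = ctx.q_org[ctx.direct_idx]
        d_o[ctx.direct_idx] = qi * (c_art - c_out[ctx.direct_idx])
        # spleen -> portal
        d_o[ctx.i_spl] = ctx.q_spleen * (c_art - c_out[ctx.i_spl])
        # liver: hepatic artery + portal in, total out, metabolism
        portal_in = wall_out.sum() + ctx.q_spleen * c_out[ctx.i_spl]
        liver_out = ctx.q_liver_total * c_out[ctx.i_liv]
        d_o[ctx.i_liv] = (
            ctx.q_ha * c_art + portal_in - liver_out
            - met_liver - met_liver_unspec
        )
        if c == 1:
            d_o[ctx.i_liv] += parent_liver_met
        # lung and blood pools
        d_o[ctx.i_lung] = ctx.co * (c_ven - c_out[ctx.i_lung])
        renal = ctx.cl_renal[c] * c_art
        d_o[ctx.i_art] = ctx.co * c_out[ctx.i_lung] - ctx.co * c_art - renal
        d_o[ctx.i_ven] = (
            (qi * c_out[ctx.direct_idx]).sum() + liver_out
            - ctx.co * c_ven + infusion[c]
        )

        # ---- assemble ----
        dy[b + _LUMEN_D.start: b + _LUMEN_D.stop] = d_d
        dy[b + _LUMEN_S.start: b + _LUMEN_S.stop] = d_s
        dy[b + _WALL.start: b + _WALL.stop] = d_w
        dy[b + _ORGANS.start: b + _ORGANS.stop] = d_o
        dy[b + _URINE] = renal
        dy[b + _GUT_MET.start: b + _GUT_MET.stop] = met_wall
        dy[b + _HEP_CYP] = met_liver
        dy[b + _HEP_UNSPEC] = met_liver_unspec
        dy[b + _PERM.start: b + _PERM.stop] = perm
        dy[b + _WALL_OUT.start: b + _WALL_OUT.stop] = wall_out
        dy[b + _LIVER_OUT] = liver_out

    return dy


def _jac_sparsity(ctx: _Context) -> lil_matrix:
    n = ctx.n_state
    S = lil_matrix((n, n), dtype=np.int8)
    il, ia, iv, ili, isp = ctx.i_lung, ctx.i_art, ctx.i_ven, ctx.i_liv, ctx.i_spl
    for c in range(2):
        b = c * _BLOCK
        D = lambda i: b + _LUMEN_D.start + i
        Ss = lambda i: b + _LUMEN_S.start + i
        W = lambda i: b + _WALL.start + i
        O = lambda i: b + _ORGANS.start + i
        for i in range(N_SEG):
            S[D(i), D(i)] = 1
            S[D(i), Ss(i)] = 1
            S[Ss(i), Ss(i)] = 1
            S[Ss(i), D(i)] = 1
            if i > 0:
                S[D(i), D(i - 1)] = 1
                S[Ss(i), Ss(i - 1)] = 1
            S[W(i), W(i)] = 1
            S[W(i), D(i)] = 1
            S[W(i), O(ia)] = 1
            S[b + _GUT_MET.start + i, W(i)] = 1
            S[b + _PERM.start + i, D(i)] = 1
            S[b + _WALL_OUT.start + i, W(i)] = 1
            S[O(ili), W(i)] = 1
        S[b + _FECAL, D(N_SEG - 1)] = 1
        S[b + _FECAL, Ss(N_SEG - 1)] = 1
        for j in ctx.direct_idx:
            S[O(j), O(j)] = 1
            S[O(j), O(ia)] = 1
            S[O(iv), O(j)] = 1
        S[O(isp), O(isp)] = 1
        S[O(isp), O(ia)] = 1
        S[O(ili), O(ili)] = 1
        S[O(ili), O(ia)] = 1
        S[O(ili), O(isp)] = 1
        S[O(il), O(il)] = 1
        S[O(il), O(iv)] = 1
        S[O(ia), O(ia)] = 1
        S[O(ia), O(il)] = 1
        S[O(iv), O(iv)] = 1
        S[O(iv), O(ili)] = 1
        S[b + _URINE, O(ia)] = 1
        S[b + _HEP_CYP, O(ili)] = 1
        S[b + _HEP_UNSPEC, O(ili)] = 1
        S[b + _LIVER_OUT, O(ili)] = 1
    # parent -> metabolite formation
    bp, bm = 0, _BLOCK
    for i in range(N_SEG):
        S[bm + _WALL.start + i, bp + _WALL.start + i] = 1
    S[bm + _ORGANS.start + ili, bp + _ORGANS.start + ili] = 1
    # enzyme coupling
    if ctx.dynamic_enzyme:
        ez = ctx.enzyme_slice.start
        for o in range(1 + N_SEG):
            S[ez + o, ez + o] = 1
        for c in range(2):
            b = c * _BLOCK
            S[b + _ORGANS.start + ili, ez] = 1
            S[b + _HEP_CYP, ez] = 1
            for i in range(N_SEG):
                S[b + _WALL.start + i, ez + 1 + i] = 1
                S[b + _GUT_MET.start + i, ez + 1 + i] = 1
        S[bm + _ORGANS.start + ili, ez] = 1
        for i in range(N_SEG):
            S[bm + _WALL.start + i, ez + 1 + i] = 1
    return S


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class TimeProfile:
    """Simulation output: time grid, full state trajectories, and views."""

    times: np.ndarray               # min
    states: np.ndarray              # (n_times, n_state)
    protocol: SimulationProtocol
    _compound_index: dict[str, int]

    # ---- views -------------------------------------------------------------
    def _ci(self, compound: str) -> int:
        try:
            return self._compound_index[compound]
        except KeyError:
            raise KeyError(f"unknown compound {compound!r}") from None

    def plasma_concentration(self, compound: str, units: str = "umol_l") -> np.ndarray:
        """Venous plasma concentration; units 'umol_l' or 'ng_ml'."""
        ci = self._ci(compound)
        v_ven = self.protocol.individual.organs["venous"].volume
        conc = self.states[:, ci * _BLOCK + _ORGANS.start + _ORG_IDX["venous"]] / v_ven
        if units == "umol_l":
            return conc
        if units == "ng_ml":
            cmp_ = (self.protocol.parent, self.protocol.metabolite)[ci]
            return conc * cmp_.MW  # µmol/L × g/mol = µg/L = ng/mL
        raise ValueError(f"unknown units {units!r}")

    def organ_amounts(self, compound: str) -> pd.DataFrame:
        ci = self._ci(compound)
        b = ci * _BLOCK
        data = {
            name: self.states[:, b + _ORGANS.start + j]
            for j, name in enumerate(ORGAN_ORDER)
        }
        for i, name in enumerate(self.protocol.individual.gut):
            data[f"gut_wall_{name.name}"] = self.states[:, b + _WALL.start + i]
        return pd.DataFrame(data, index=self.times)

    def ledger(self, compound: str) -> dict[str, np.ndarray]:
        ci = self._ci(compound)
        b = ci * _BLOCK
        s = self.states
        return {
            "urine": s[:, b + _URINE],
            "gut_wall_metabolism": s[:, b + _GUT_MET.start: b + _GUT_MET.stop].sum(axis=1),
            "gut_wall_metabolism_per_segment": s[:, b + _GUT_MET.start: b + _GUT_MET.stop],
            "hepatic_cyp3a4_metabolism": s[:, b + _HEP_CYP],
            "hepatic_unspecific_clearance": s[:, b + _HEP_UNSPEC],
            "permeated": s[:, b + _PERM.start: b + _PERM.stop].sum(axis=1),
            "permeated_per_segment": s[:, b + _PERM.start: b + _PERM.stop],
            "fecal": s[:, b + _FECAL],
            "gut_wall_outflow": s[:, b + _WALL_OUT.start: b + _WALL_OUT.stop],
            "liver_outflow": s[:, b + _LIVER_OUT],
        }

    def luminal_state(self, time_index: int, compound: str) -> absorption.LuminalState:
        ci = self._ci(compound)
        b = ci * _BLOCK
        row = self.states[time_index]
        return absorption.LuminalState(
            undissolved=np.clip(row[b + _LUMEN_S.start: b + _LUMEN_S.stop], 0, None),
            dissolved=np.clip(row[b + _LUMEN_D.start: b + _LUMEN_D.stop], 0, None),
            permeated=row[b + _PERM.start: b + _PERM.stop],
            fecal=max(float(row[b + _FECAL]), 0.0),
        )

    def system_amount(self, compound: str) -> np.ndarray:
        """Total amount currently in lumen + wall + organs (µmol)."""
        ci = self._ci(compound)
        b = ci * _BLOCK
        s = self.states
        return (
            s[:, b + _LUMEN_D.start: b + _LUMEN_D.stop].sum(axis=1)
            + s[:, b + _LUMEN_S.start: b + _LUMEN_S.stop].sum(axis=1)
            + s[:, b + _WALL.start: b + _WALL.stop].sum(axis=1)
            + s[:, b + _ORGANS.start: b + _ORGANS.stop].sum(axis=1)
        )

    # ---- doses --------------------------------------------------------------
    def dosed_umol(self, compound: str) -> np.ndarray:
        """Cumulative administered amount at each output time (µmol)."""
        ci = self._ci(compound)
        cmp_ = (self.protocol.parent, self.protocol.metabolite)[ci]
        dosed = np.zeros_like(self.times)
        for e in self.protocol.events:
            if e.compound != compound:
                continue
            amt = cmp_.mg_to_umol(e.dose)
            if e.route == "oral":
                dosed += amt * (self.times >= e.start_time)
            else:
                frac = np.clip(
                    (self.times - e.start_time) / e.infusion_duration, 0.0, 1.0
                )
                dosed += amt * frac
        return dosed

    def oral_dose_umol(self, compound: str) -> float:
        ci = self._ci(compound)
        cmp_ = (self.protocol.parent, self.protocol.metabolite)[ci]
        return sum(
            cmp_.mg_to_umol(e.dose)
            for e in self.protocol.events
            if e.compound == compound and e.route == "oral"
        )

    # ---- invariants ----------------------------------------------------------
    def mass_balance_error(self) -> float:
        """Maximum relative global molar mass-balance error over all output
        times: parent + metabolite system amounts + terminal ledgers vs dosed
        moles (parent CYP3A4 turnover conserves moles 1:1)."""
        parent, met = self.protocol.parent.name, self.protocol.metabolite.name
        lp, lm = self.ledger(parent), self.ledger(met)
        accounted = (
            self.system_amount(parent) + lp["urine"] + lp["fecal"]
            + self.system_amount(met) + lm["urine"] + lm["fecal"]
            + lm["gut_wall_metabolism"] + lm["hepatic_cyp3a4_metabolism"]
            + lm["hepatic_unspecific_clearance"]
        )
        dosed = self.dosed_umol(parent) + self.dosed_umol(met)
        scale = max(dosed.max(), 1e-12)
        mask = dosed > 0
        if not mask.any():
            return 0.0
        return float(np.max(np.abs(accounted[mask] - dosed[mask])) / scale)

    # ---- export ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self._compound_index:
            rows.append(pd.DataFrame({
                "time_min": self.times,
                "compound": name,
                "compartment": "venous_plasma",
                "concentration_umol_L": self.plasma_concentration(name),
                "concentration_ng_mL": self.plasma_concentration(name, "ng_ml"),
            }))
        return pd.concat(rows, ignore_index=True)

    def ledger_frame(self) -> pd.DataFrame:
        rows = []
        for name in self._compound_index:
            led = self.ledger(name)
            for key in ("urine", "gut_wall_metabolism", "hepatic_cyp3a4_metabolism",
                        "hepatic_unspecific_clearance", "permeated", "fecal"):
                rows.append(pd.DataFrame({
                    "time_min": self.times,
                    "compound": name,
                    "ledger": key,
                    "amount_umol": led[key],
                }))
        return pd.concat(rows, ignore_index=True)

    def dissolution_profile(self, compound: str) -> pd.DataFrame:
        """Fraction of the oral dose dissolved (in solution, absorbed, or
        transited) vs time, mirroring in vivo dissolution evaluation."""
        dose = self.oral_dose_umol(compound)
        if dose <= 0:
            raise ValueError("no oral dose administered")
        ci = self._ci(compound)
        b = ci * _BLOCK
        solid = self.states[:, b + _LUMEN_S.start: b + _LUMEN_S.stop].sum(axis=1)
        dosed = self.dosed_umol(compound)
        frac = np.where(dosed > 0, (dosed - solid) / np.maximum(dosed, 1e-12), 0.0)
        return pd.DataFrame({"time_min": self.times, "fraction_dissolved": frac})


def simulate(protocol: SimulationProtocol) -> TimeProfile:
    """Integrate the coupled parent-metabolite whole-body system.

    Deterministic for fixed inputs; the integration restarts at every dosing
    boundary so event discontinuities are never straddled.
    """
    ctx = _Context(protocol)

    # event breakpoints
    breaks = {0.0, protocol.duration}
    for e in protocol.events:
        breaks.add(e.start_time)
        if e.route == "iv_infusion":
            breaks.add(min(e.start_time + e.infusion_duration, protocol.duration))
    breaks = sorted(b for b in breaks if 0.0 <= b <= protocol.duration)

    grid = np.arange(0.0, protocol.duration + 1e-9, protocol.output_grid)
    grid = np.unique(np.concatenate([grid, np.array(breaks), [protocol.duration]]))

    y = np.zeros(ctx.n_state)
    if ctx.dynamic_enzyme:
        e_init = ctx.e0_vec.copy()
        if protocol.induction_at_steady_state:
            comp, mbi, ind_f = ctx.exposure_terms(0.0)
            has_ind = any(
                p.interaction.mechanism == "induction" for p in ctx.perps
            )
            if has_ind:
                # perpetrator pretreatment: start from the perturbed steady state
                e_init = ctx.kdeg * ctx.e0_vec * ind_f / (ctx.kdeg + mbi)
        y[ctx.enzyme_slice] = e_init

    sparsity = _jac_sparsity(ctx)
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []

    for ta, tb in zip(breaks[:-1], breaks[1:]):
        # apply bolus oral doses at segment start
        for e in protocol.events:
            if e.start_time == ta and e.route == "oral":
                ci = ctx.compound_index[e.compound]
                amt = ctx.compounds[ci].mg_to_umol(e.dose)
                b = ci * _BLOCK
                if e.formulation.kind == "oral_solution":
                    y[b + _LUMEN_D.start] += amt      # stomach, pre-dissolved
                else:
                    y[b + _LUMEN_S.start] += amt      # stomach, solid
                ctx.current_oral[ci] = (ta, e.formulation)

        infusion = np.zeros(2)
        for e in protocol.events:
            if e.route == "iv_infusion" and e.start_time <= ta < e.start_time + e.infusion_duration:
                ci = ctx.compound_index[e.compound]
                infusion[ci] += ctx.compounds[ci].mg_to_umol(e.dose) / e.infusion_duration

        t_eval = grid[(grid >= ta) & (grid <= tb)]
        if t_eval.size == 0 or t_eval[0] > ta:
            t_eval = np.concatenate([[ta], t_eval])
        if t_eval[-1] < tb:
            t_eval = np.concatenate([t_eval, [tb]])

        sol = solve_ivp(
            _rhs, (ta, tb), y,
            method="BDF",
            t_eval=t_eval,
            rtol=RTOL, atol=ATOL,
            jac_sparsity=sparsity,
            args=(ctx, infusion),
        )
        if not sol.success:
            raise SolverError(f"ODE solver failed: {sol.message}", sol.t[-1] if sol.t.size else ta, y)
        y = sol.y[:, -1].copy()
        times_out.append(sol.t)
        states_out.append(sol.y.T)

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    times, idx = np.unique(times, return_index=True)
    states = states[idx]

    return TimeProfile(
        times=times,
        states=states,
        protocol=protocol,
        _compound_index={protocol.parent.name: 0, protocol.metabolite.name: 1},
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def bioavailability(
    oral: TimeProfile,
    iv: TimeProfile,
    oral_dose: float,
    iv_dose: float,
    compound: str = "felodipine",
) -> float:
    """Absolute oral bioavailability from dose-normalized AUC_last ratio,
    evaluated to the last common output time (no extrapolation)."""
    t_last = min(oral.times[-1], iv.times[-1])
    t_first = max(oral.times[0], iv.times[0])
    if t_last <= t_first:
        raise ValueError("profiles have no overlapping time range")
    auc = []
    for prof, dose in ((oral, oral_dose), (iv, iv_dose)):
        mask = prof.times <= t_last
        t = prof.times[mask]
        c = prof.plasma_concentration(compound)[mask]
        auc.append(np.trapezoid(c, t) / dose)
    if auc[1] <= 0:
        raise ValueError("iv reference AUC is zero")
    return float(auc[0] / auc[1])


def sequential_availabilities(profile: TimeProfile, compound: str = "felodipine") -> dict:
    """Ledger-based decomposition of oral bioavailability into sequential
    availabilities F = fa × F_gut × F_hepatic.

    In the linear regime every input stream to a well-stirred compartment
    shares the same fate fractions, so per-segment gut-wall extraction is
    metabolized/(metabolized + outflow) from the cumulative ledgers, and
    hepatic extraction likewise.
    """
    led = profile.ledger(compound)
    dose = profile.oral_dose_umol(compound)
    perm = led["permeated_per_segment"][-1]
    met = led["gut_wall_metabolism_per_segment"][-1]
    out = led["gut_wall_outflow"][-1]
    fa = perm.sum() / dose if dose > 0 else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        e_seg = np.where(met + out > 0, met / (met + out), 0.0)
    f_gut = float((perm * (1.0 - e_seg)).sum() / perm.sum()) if perm.sum() > 0 else 1.0
    hep = led["hepatic_cyp3a4_metabolism"][-1] + led["hepatic_unspecific_clearance"][-1]
    liv_out = led["liver_outflow"][-1]
    e_h = hep / (hep + liv_out) if hep + liv_out > 0 else 0.0
    return {
        "fa": float(fa),
        "f_gut": f_gut,
        "f_hepatic": float(1.0 - e_h),
        "F": float(fa * f_gut * (1.0 - e_h)),
        "gut_extraction_per_segment": e_seg,
        "hepatic_extraction": float(e_h),
    }
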