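"""Non-compartmental analysis and model-evaluation statistics.

Implements the standard open-systems-pharmacology definitions:

* AUC_last — linear trapezoid from dosing to the last observation;
* C_max — maximum observed/predicted value;
* MRD — mean relative deviation, ``10^sqrt(mean((log10 pred − log10 obs)²))``;
* GMFE — geometric mean fold error, ``10^mean(|log10(pred/obs)|)``;
* Guest limits — DDI-ratio prediction-success bounds that tighten toward
  1.25-fold at an observed ratio of 1 and widen to the classic 2-fold for
  large ratios;

plus a seeded multi-start least-squares parameter-fitting routine
(Latin-hypercube starts, trust-region-reflective local optimization).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import pd_model
from .engine import SimulationProtocol, TimeProfile, simulate

__all__ = [
    "ObservedSeries",
    "auc_last",
    "cmax",
    "mrd",
    "gmfe",
    "guest_limits",
    "fit_parameters",
    "FitResult",
    "read_observed_series",
    "write_observed_series",
]

log = logging.getLogger(__name__)

SERIES_KINDS = ("concentration", "dbp", "hr")
#: Guest et al. variability term; limits at observed ratio 1 are
#: (1/1.25, 1.25) and approach the classic 2-fold for large ratios.
GUEST_DELTA = 1.25


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ObservedSeries:
    """An observed (or synthetic) time series.

    Concentrations in ng/mL, blood pressure in mmHg, heart rate in bpm;
    times in minutes after first dose.  ``below_lloq`` flags censored points
    (their stored value is the LLOQ).
    """

    times: tuple
    values: tuple
    kind: str = "concentration"
    compound: Optional[str] = "felodipine"
    lloq: Optional[float] = None
    below_lloq: tuple = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.size != v.size:
            raise MetricsError("times and values must have the same length")
        if t.size and np.any(np.diff(t) <= 0):
            raise MetricsError("times must be strictly increasing")
        if self.kind not in SERIES_KINDS:
            raise MetricsError(f"unknown series kind {self.kind!r}")
        flags = self.below_lloq or tuple(False for _ in self.times)
        if len(flags) != t.size:
            raise MetricsError("below_lloq mask length mismatch")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))
        object.__setattr__(self, "below_lloq", tuple(bool(b) for b in flags))
        if any(v < 0 and not b for v, b in zip(self.values, self.below_lloq)):
            raise MetricsError("negative values must be flagged below-LLOQ")

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, float)

    @property
    def values_array(self) -> np.ndarray:
        return np.asarray(self.values, float)


def _as_times_values(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, ObservedSeries):
        return series.times_array, series.values_array
    t, v = series
    return np.asarray(t, float), np.asarray(v, float)


def auc_last(series) -> float:
    """Linear-trapezoid AUC from the first to the last point (units·min)."""
    t, v = _as_times_values(series)
    if t.size < 2:
        raise MetricsError("AUC needs at least two points")
    return float(np.trapezoid(v, t))


def cmax(series) -> float:
    t, v = _as_times_values(series)
    if v.size < 1:
        raise MetricsError("empty series")
    return float(v.max())


def _interp_log(pred_times, pred_values, obs_times) -> np.ndarray:
    """Interpolate a prediction to observation times, linear in log10."""
    pv = np.clip(np.asarray(pred_values, float), 1e-300, None)
    return 10.0 ** np.interp(obs_times, pred_times, np.log10(pv))


def mrd(pred, obs: ObservedSeries, impute_lloq_half: bool = False) -> float:
    """Mean relative deviation of a prediction from observations:
    MRD = 10^sqrt(Σ(log10 pred_i − log10 obs_i)² / n) ≥ 1.

    Below-LLOQ observations are excluded unless ``impute_lloq_half`` is set,
    in which case they enter as LLOQ/2.  The prediction is interpolated to
    the observation times, linearly in log concentration.
    """
    pt, pv = _as_times_values(pred)
    t = obs.times_array
    v = obs.values_array.copy()
    mask = ~np.asarray(obs.below_lloq, bool)
    if impute_lloq_half and obs.lloq is not None:
        v[~mask] = obs.lloq / 2.0
        mask = np.ones_like(mask)
    mask &= v > 0
    if not mask.any():
        raise MetricsError("no usable observation/prediction pairs")
    pred_at_obs = _interp_log(pt, pv, t[mask])
    resid = np.log10(pred_at_obs) - np.log10(v[mask])
    return float(10.0 ** np.sqrt(np.mean(resid**2)))


def gmfe(pairs: Sequence[tuple[float, float]]) -> float:
    """Geometric mean fold error of (predicted, observed) scalar pairs:
    GMFE = 10^(Σ|log10(pred/obs)|/n) ≥ 1."""
    if not len(pairs):
        raise MetricsError("no pairs supplied")
    logs = []
    for p, o in pairs:
        if p <= 0 or o <= 0:
            raise MetricsError("pairs must be positive")
        logs.append(abs(np.log10(p / o)))
    return float(10.0 ** np.mean(logs))


def guest_limits(observed_ratio: float, delta: float = GUEST_DELTA) -> tuple[float, float]:
    """Prediction-success limits for a DDI AUC or C_max ratio.

    With R = max(ratio, 1/ratio), the fold-limit is L = (δ + 2(R−1))/R and
    the acceptable predicted-ratio interval is (ratio/L, ratio·L) — symmetric
    on the log scale, tightening to δ-fold as the observed ratio approaches 1
    and approaching the classic 2-fold for strong interactions.
    """
    if observed_ratio <= 0:
        raise MetricsError("observed ratio must be > 0")
    r = max(observed_ratio, 1.0 / observed_ratio)
    limit = (delta + 2.0 * (r - 1.0)) / r
    return observed_ratio / limit, observed_ratio * limit


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------


@dataclass
class PDSettings:
    """Bundle of PD parameters used when fitting effect observations."""

    bp: pd_model.CircadianBPParameters = field(default_factory=pd_model.healthy_bp_parameters)
    hr: pd_model.CircadianHRParameters = field(default_factory=pd_model.healthy_hr_parameters)
    bp_effect: pd_model.EmaxParameters = field(default_factory=pd_model.bp_emax_parameters)
    hr_effect: pd_model.EmaxParameters = field(default_factory=pd_model.hr_emax_parameters)
    clock_offset: float = pd_model.DEFAULT_DOSING_CLOCK_TIME_H


@dataclass
class FitResult:
    values: dict[str, float]
    objective: float              # sum of squared residuals at the optimum
    nominal_objective: float
    n_starts_run: int
    flat_objective: bool
    success: bool


_PD_TARGETS = {"bp", "hr", "bp_effect", "hr_effect"}


def _apply_parameters(
    protocol: SimulationProtocol, pd_settings: PDSettings, values: dict[str, float]
) -> tuple[SimulationProtocol, PDSettings]:
    prot = protocol
    pdset = dataclasses.replace(pd_settings)
    for path, val in values.items():
        parts = path.split(".")
        if parts[0] in ("parent", "metabolite"):
            cmp_ = getattr(prot, parts[0])
            prot = dataclasses.replace(prot, **{parts[0]: dataclasses.replace(cmp_, **{parts[1]: val})})
        elif parts[0] == "protocol":
            prot = dataclasses.replace(prot, **{parts[1]: val})
        elif parts[0] == "pd" and len(parts) == 3 and parts[1] in _PD_TARGETS:
            obj = getattr(pdset, parts[1])
            setattr(pdset, parts[1], dataclasses.replace(obj, **{parts[2]: val}))
        else:
            raise MetricsError(f"unknown parameter path {path!r}")
    return prot, pdset


def _residuals(
    protocol: SimulationProtocol,
    pd_settings: PDSettings,
    observations: Sequence[ObservedSeries],
    cached_profile: Optional[TimeProfile] = None,
) -> np.ndarray:
    profile = cached_profile if cached_profile is not None else simulate(protocol)
    res: list[np.ndarray] = []
    pd_frame = None
    for obs in observations:
        t = obs.times_array
        mask = ~np.asarray(obs.below_lloq, bool) & (obs.values_array > 0) \
            if obs.kind == "concentration" else np.ones(t.size, bool)
        if obs.kind == "concentration":
            pred = _interp_log(
                profile.times,
                profile.plasma_concentration(obs.compound, units="ng_ml"),
                t[mask],
            )
            res.append(np.log(pred) - np.log(obs.values_array[mask]))
        else:
            if pd_frame is None:
                pd_frame = pd_model.predict_pd(
                    profile, pd_settings.bp, pd_settings.hr,
                    pd_settings.bp_effect, pd_settings.hr_effect,
                    clock_offset=pd_settings.clock_offset,
                )
            col = "dbp_mmHg" if obs.kind == "dbp" else "heart_rate_bpm"
            pred = np.interp(t, pd_frame["time_min"], pd_frame[col])
            res.append(pred - obs.values_array)
    if not res:
        raise MetricsError("no observations supplied")
    return np.concatenate(res)


def fit_parameters(
    protocol: SimulationProtocol,
    free_parameters: dict[str, tuple[float, float]],
    observations: Sequence[ObservedSeries],
    n_starts: int = 20,
    seed: int = 0,
    pd_settings: Optional[PDSettings] = None,
    early_stop_rms: Optional[float] = None,
    extra_protocols: Sequence[tuple[SimulationProtocol, Sequence[ObservedSeries]]] = (),
) -> FitResult:
    """Multi-start local least squares (Latin-hypercube starts, deterministic
    for a fixed seed).

    Concentration observations contribute squared log-residuals; effect
    observations squared plain residuals.  When every free parameter lives in
    the PD layer the concentration profile is simulated once and reused.
    ``early_stop_rms`` stops the multi-start loop once a local optimum with an
    RMS residual below the threshold is found (useful for noiseless
    self-consistency fits).  ``extra_protocols`` adds further (protocol,
    observations) blocks sharing the same free parameters (e.g. iv + oral).
    """
    pdset = pd_settings or PDSettings()
    blocks = [(protocol, tuple(observations))] + [
        (p, tuple(o)) for p, o in extra_protocols
    ]

    names = list(free_parameters)
    pd_only = bool(names) and all(n.startswith("pd.") for n in names)
    cached = [simulate(p) for p, _ in blocks] if (pd_only or not names) else [None] * len(blocks)

    def objective_residuals(x: np.ndarray) -> np.ndarray:
        vals = dict(zip(names, x))
        out = []
        for (prot, obs), cache in zip(blocks, cached):
            prot2, pdset2 = _apply_parameters(prot, pdset, vals)
            out.append(_residuals(prot2, pdset2, obs, cached_profile=cache))
        return np.concatenate(out)

    nominal_res = objective_residuals(np.array([
        _nominal_value(protocol, pdset, n) for n in names
    ])) if names else objective_residuals(np.array([]))
    nominal_obj = float(np.sum(nominal_res**2))

    if not names:
        return FitResult({}, nominal_obj, nominal_obj, 0, False, True)

    lo = np.array([free_parameters[n][0] for n in names])
    hi = np.array([free_parameters[n][1] for n in names])
    if np.any(hi <= lo):
        raise MetricsError("free parameters need finite bounds with lo < hi")

    x_nom = np.clip(
        [_nominal_value(protocol, pdset, n) for n in names], lo, hi
    )
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = [x_nom]
    if n_starts > 1:
        unit = sampler.random(n_starts - 1)
        starts += list(lo + unit * (hi - lo))

    best_x, best_cost = None, np.inf
    objectives = []
    n_run = 0
    n_res = nominal_res.size
    for x0 in starts:
        n_run += 1
        try:
            res = least_squares(objective_residuals, x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # solver failure inside one start
            log.debug("fit start failed: %s", exc)
            continue
        cost = float(np.sum(res.fun**2))
        objectives.append(cost)
        if cost < best_cost:
            best_cost, best_x = cost, res.x.copy()
        if early_stop_rms is not None and np.sqrt(cost / n_res) < early_stop_rms:
            break

    if best_x is None:
        return FitResult({}, np.inf, nominal_obj, n_run, False, False)

    flat = False
    if len(objectives) >= 3:
        spread = max(objectives) - min(objectives)
        if spread < 1e-12 * (1.0 + min(objectives)) and nominal_obj <= min(objectives) * (1 + 1e-9):
            flat = True
            warnings.warn(
                "objective is insensitive to the requested parameters "
                "(flat objective); estimates are not identifiable"
            )

    return FitResult(dict(zip(names, best_x)), best_cost, nominal_obj, n_run, flat, True)


def _nominal_value(protocol: SimulationProtocol, pdset: PDSettings, path: str) -> float:
    parts = path.split(".")
    if parts[0] in ("parent", "metabolite"):
        return float(getattr(getattr(protocol, parts[0]), parts[1]))
    if parts[0] == "protocol":
        return float(getattr(protocol, parts[1]))
    if parts[0] == "pd":
        return float(getattr(getattr(pdset, parts[1]), parts[2]))
    raise MetricsError(f"unknown parameter path {path!r}")


# ---------------------------------------------------------------------------
# delimited-text I/O for observed series
# ---------------------------------------------------------------------------


def write_observed_series(series: Sequence[ObservedSeries], path: str | Path) -> None:
    rows = []
    for i, s in enumerate(series):
        for t, v, b in zip(s.times, s.values, s.below_lloq):
            rows.append({
                "series": i, "kind": s.kind, "compound": s.compound or "",
                "time_min": t, "value": v,
                "lloq": s.lloq if s.lloq is not None else "",
                "below_lloq": int(b),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observed_series(path: str | Path) -> list[ObservedSeries]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("series", sort=True):
        lloq = grp["lloq"].iloc[0]
        lloq = None if pd.isna(lloq) or lloq == "" else float(lloq)
        out.append(ObservedSeries(
            times=tuple(grp["time_min"]),
            values=tuple(grp["value"]),
            kind=str(grp["kind"].iloc[0]),
            compound=str(grp["compound"].iloc[0]) or None,
            lloq=lloq,
            below_lloq=tuple(bool(b) for b in grp["below_lloq"]),
        ))
    return out
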