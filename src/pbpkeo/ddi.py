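"""CYP-mediated drug–drug interaction scenarios for osimertinib.

Perpetrators are reduced exposure models (one-compartment, first-order
absorption, linear clearance): the victim only sees unbound perpetrator
concentration at the enzyme, so a full mechanistic perpetrator model adds
nothing to enzyme-level multipliers.  Competitive inhibition multiplies an
enzyme's intrinsic clearance by 1/(1 + I_u/Ki_u); induction raises the
enzyme amount through a turnover model

    dE/dt = kdeg_enz · (E0·(1 + Emax·I_u/(EC50_u + I_u)) − E)

so induction onsets over the enzyme turnover half-life (default 36 h for
CYP3A4) while inhibition is instantaneous.  Intestinal CYP3A4 receives the
same multiplier as hepatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .parameters import CYP_ENZYMES, ModelParams
from .pbpk import (
    MEAN_SUBJECT,
    BodyModel,
    DoseRegimen,
    SimulationResult,
    SolverConfig,
    VirtualSubject,
    simulate_events,
)

PERPETRATOR_NAMES = ("itraconazole", "fluconazole", "fluvoxamine",
                     "rifampicin", "efavirenz")
SHORT_NAMES = {"ITR": "itraconazole", "FLUC": "fluconazole",
               "FLUV": "fluvoxamine", "RIF": "rifampicin", "EFA": "efavirenz"}


@dataclass(frozen=True)
class PerpetratorModel:
    name: str
    dose_mg: float
    interval_h: float
    molecular_weight: float
    oral_clearance_l_h: float      # CL/F
    volume_l: float                # V/F
    ka_per_h: float
    fu: float
    inhibition: dict = field(default_factory=dict)   # enzyme -> ki_u (µM)
    induction: dict = field(default_factory=dict)    # enzyme -> (emax, ec50_u)
    kdeg_enzyme_per_h: float = np.log(2.0) / 36.0

    def __post_init__(self):
        for ki in self.inhibition.values():
            if ki <= 0:
                raise ValueError("ki_u must be > 0")
        for emax, ec50 in self.induction.values():
            if emax < 0 or ec50 <= 0:
                raise ValueError("emax must be >= 0 and ec50_u > 0")


def load_perpetrators(path: str | Path | None = None) -> dict:
    p = Path(path) if path else Path(str(resources.files("pbpkeo").joinpath(
        "data", "perpetrators.yaml")))
    raw = yaml.safe_load(p.read_text())
    kdeg = np.log(2.0) / float(raw.get("enzyme_turnover_halflife_h", 36.0))
    out = {}
    for name in PERPETRATOR_NAMES:
        rec = raw[name]
        out[name] = PerpetratorModel(
            name=name,
            dose_mg=float(rec["regimen"]["dose_mg"]),
            interval_h=float(rec["regimen"]["interval_h"]),
            molecular_weight=float(rec["molecular_weight"]),
            oral_clearance_l_h=float(rec["oral_clearance_L_h"]),
            volume_l=float(rec["volume_L"]),
            ka_per_h=float(rec["ka_per_h"]),
            fu=float(rec["fu"]),
            inhibition={k: float(v["ki_u_uM"])
                        for k, v in rec.get("inhibition", {}).items()},
            induction={k: (float(v["emax_fold"]), float(v["ec50_u_uM"]))
                       for k, v in rec.get("induction", {}).items()},
            kdeg_enzyme_per_h=kdeg,
        )
    return out


def perpetrator_unbound_profile(p: PerpetratorModel, time_h: np.ndarray,
                                dosing_start_h: float = 0.0,
                                dosing_end_h: float | None = None) -> np.ndarray:
    """Unbound perpetrator concentration (µM) by closed-form superposition.

    One-compartment oral model per dose:
    C(t) = F·D/V · ka/(ka−ke) · (e^{−ke·t} − e^{−ka·t}), summed over doses
    between ``dosing_start_h`` and ``dosing_end_h``.
    """
    time_h = np.asarray(time_h, float)
    ke = p.oral_clearance_l_h / p.volume_l
    ka = p.ka_per_h
    dose_um_l = p.dose_mg / p.molecular_weight * 1000.0 / p.volume_l  # µmol/L
    end = dosing_end_h if dosing_end_h is not None else time_h[-1]
    conc = np.zeros_like(time_h)
    t_dose = dosing_start_h
    while t_dose < end - 1.0e-9:
        dt = time_h - t_dose
        mask = dt > 0
        conc[mask] += dose_um_l * ka / (ka - ke) * (
            np.exp(-ke * dt[mask]) - np.exp(-ka * dt[mask]))
        t_dose += p.interval_h
    return conc * p.fu


@dataclass
class InteractionEffect:
    """Per-enzyme time-varying clearance multipliers and their decomposition."""
    time_h: np.ndarray
    inhibition: dict      # enzyme -> array in (0, 1]
    induction: dict       # enzyme -> array >= 1
    combined: dict        # enzyme -> inhibition × induction

    def multiplier_fn(self):
        t, comb = self.time_h, self.combined
        def fn(time):
            return {enz: float(np.interp(time, t, arr)) for enz, arr in comb.items()}
        return fn


def apply_interaction(p: PerpetratorModel, time_h: np.ndarray,
                      i_u_um: np.ndarray) -> InteractionEffect:
    """Turn an unbound perpetrator profile into per-enzyme multipliers."""
    time_h = np.asarray(time_h, float)
    i_u = np.asarray(i_u_um, float)
    inhibition, induction = {}, {}
    for enz, ki in p.inhibition.items():
        inhibition[enz] = 1.0 / (1.0 + i_u / ki)
    for enz, (emax, ec50) in p.induction.items():
        # enzyme turnover toward the Emax-driven production target
        target = 1.0 + emax * i_u / (ec50 + i_u)
        kdeg = p.kdeg_enzyme_per_h
        def rhs(t, y, tt=time_h, tg=target):
            return kdeg * (np.interp(t, tt, tg) - y[0])
        sol = solve_ivp(rhs, (time_h[0], time_h[-1]), [1.0], t_eval=time_h,
                        method="LSODA", rtol=1.0e-8, atol=1.0e-10)
        if not sol.success:
            raise RuntimeError(f"induction turnover integration failed: {sol.message}")
        induction[enz] = np.maximum(sol.y[0], 1.0 - 1e-12)
    combined = {}
    for enz in CYP_ENZYMES:
        m = np.ones_like(time_h)
        if enz in inhibition:
            m = m * inhibition[enz]
        if enz in induction:
            m = m * induction[enz]
        if enz in inhibition or enz in induction:
            combined[enz] = m
    return InteractionEffect(time_h=time_h, inhibition=inhibition,
                             induction=induction, combined=combined)


@dataclass
class DDIScenarioResult:
    perpetrator: str
    auc_ratio: float
    cmax_ratio: float
    baseline: SimulationResult
    perturbed: SimulationResult
    effect: InteractionEffect | None


def _final_interval_metrics(res: SimulationResult, interval_h: float,
                            at_time_h: float | None = None):
    t_end = at_time_h if at_time_h is not None else res.time_h[-1]
    mask = (res.time_h >= t_end - interval_h - 1e-9) & (res.time_h <= t_end + 1e-9)
    t, c = res.time_h[mask], res.plasma_nmol_l[mask]
    return float(np.trapezoid(c, t)), float(np.max(c))


def ddi_scenario(params: ModelParams, perpetrator: PerpetratorModel | None,
                 osi_regimen: DoseRegimen, hepatic_calibration: float,
                 brain_ps: float, subject: VirtualSubject = MEAN_SUBJECT,
                 perp_start_h: float = 0.0,
                 solver: SolverConfig | None = None) -> DDIScenarioResult:
    """Co-administration for the regimen horizon; ratios on the final interval."""
    horizon = osi_regimen.horizon_h
    base_model = BodyModel(params, hepatic_calibration=hepatic_calibration,
                           brain_ps=brain_ps, subject=subject)
    baseline = simulate_events(base_model, osi_regimen.events(), horizon, solver=solver)

    effect = None
    if perpetrator is None:
        perturbed = baseline
    else:
        grid = np.arange(0.0, horizon + 1e-9, 0.25)
        i_u = perpetrator_unbound_profile(perpetrator, grid, dosing_start_h=perp_start_h)
        effect = apply_interaction(perpetrator, grid, i_u)
        ddi_model = BodyModel(params, hepatic_calibration=hepatic_calibration,
                              brain_ps=brain_ps, subject=subject,
                              enzyme_multiplier=effect.multiplier_fn())
        perturbed = simulate_events(ddi_model, osi_regimen.events(), horizon, solver=solver)

    auc0, cmax0 = _final_interval_metrics(baseline, osi_regimen.interval)
    auc1, cmax1 = _final_interval_metrics(perturbed, osi_regimen.interval)
    return DDIScenarioResult(
        perpetrator=perpetrator.name if perpetrator else "none",
        auc_ratio=auc1 / auc0, cmax_ratio=cmax1 / cmax0,
        baseline=baseline, perturbed=perturbed, effect=effect)


def single_dose_itraconazole_study(params: ModelParams, perp: PerpetratorModel,
                                   hepatic_calibration: float, brain_ps: float,
                                   solver: SolverConfig | None = None) -> dict:
    """Published single-dose calendar: victim 80 mg on days 1 and 10,
    itraconazole 200 mg BID on days 6–18; AUC/Cmax of dose 10 vs dose 1."""
    horizon = 20.0 * 24.0
    events = [(0.0, 80.0), (9.0 * 24.0, 80.0)]
    base = BodyModel(params, hepatic_calibration=hepatic_calibration, brain_ps=brain_ps)
    alone = simulate_events(base, [(0.0, 80.0)], 9.0 * 24.0, solver=solver)
    grid = np.arange(0.0, horizon + 1e-9, 0.25)
    i_u = perpetrator_unbound_profile(perp, grid, dosing_start_h=5.0 * 24.0,
                                      dosing_end_h=18.0 * 24.0)
    effect = apply_interaction(perp, grid, i_u)
    model = BodyModel(params, hepatic_calibration=hepatic_calibration,
                      brain_ps=brain_ps, enzyme_multiplier=effect.multiplier_fn())
    combo = simulate_events(model, events, horizon, solver=solver)

    def window_metrics(res, start, width):
        mask = (res.time_h >= start - 1e-9) & (res.time_h <= start + width + 1e-9)
        t, c = res.time_h[mask], res.plasma_nmol_l[mask]
        return float(np.trapezoid(c, t)), float(np.max(c))

    width = 9.0 * 24.0   # identical post-dose windows for both occasions
    auc_a, cmax_a = window_metrics(alone, 0.0, width)
    auc_c, cmax_c = window_metrics(combo, 9.0 * 24.0, width)
    return {"auc_ratio": auc_c / auc_a, "cmax_ratio": cmax_c / cmax_a}


def repeated_dose_rifampicin_study(params: ModelParams, perp: PerpetratorModel,
                                   hepatic_calibration: float, brain_ps: float,
                                   solver: SolverConfig | None = None) -> dict:
    """Published repeated-dose calendar: victim 80 mg OD on days 1–29,
    rifampicin 600 mg OD on days 6–30; final-interval AUC/Cmax of the
    co-administered run vs the victim alone."""
    regimen = DoseRegimen(80.0, 24.0, 29)
    base = BodyModel(params, hepatic_calibration=hepatic_calibration, brain_ps=brain_ps)
    alone = simulate_events(base, regimen.events(), regimen.horizon_h, solver=solver)
    grid = np.arange(0.0, regimen.horizon_h + 1e-9, 0.25)
    i_u = perpetrator_unbound_profile(perp, grid, dosing_start_h=5.0 * 24.0)
    effect = apply_interaction(perp, grid, i_u)
    model = BodyModel(params, hepatic_calibration=hepatic_calibration,
                      brain_ps=brain_ps, enzyme_multiplier=effect.multiplier_fn())
    combo = simulate_events(model, regimen.events(), regimen.horizon_h, solver=solver)
    auc_a, cmax_a = _final_interval_metrics(alone, 24.0)
    auc_c, cmax_c = _final_interval_metrics(combo, 24.0)
    return {"auc_ratio": auc_c / auc_a, "cmax_ratio": cmax_c / cmax_a}


def null_perpetrator(name: str = "null") -> PerpetratorModel:
    """A perpetrator with no interaction terms; all ratios must be 1."""
    return PerpetratorModel(name=name, dose_mg=100.0, interval_h=24.0,
                            molecular_weight=300.0, oral_clearance_l_h=10.0,
                            volume_l=100.0, ka_per_h=1.0, fu=0.5)
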