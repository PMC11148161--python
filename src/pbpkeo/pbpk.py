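"""Reduced whole-body PBPK model of osimertinib.

Structure: oral dosing with Weibull dissolution in the stomach, first-order
gastric emptying (mean time GET) and first-order intestinal absorption scaled
from Peff; flow-limited organs with Rodgers–Rowland partition coefficients
(moderate-to-strong base branch) scaled by the global Kp scale; six-CYP
hepatic plus intestinal CYP3A4 metabolism; renal clearance GFR × fup; and a
permeability-limited brain with four sub-compartments (vascular plasma,
blood cells, interstitial, intracellular) with passive BBB permeability and
ABCB1/BCRP efflux.

Conventions
-----------
* State vector holds amounts in µmol; concentrations are µmol/L (µM).
* Organ Kp is tissue:plasma on total concentrations; venous outflow blood
  concentration of a flow-limited organ is C_t·Rbp/Kp.
* The brain interstitial space is assigned the same protein-binding milieu
  as plasma, so passive BBB exchange written on unbound concentrations
  reduces to PS·fu·(C_vascular,plasma − C_interstitial) on totals, and the
  unbound interstitial:unbound plasma ratio Kp,uu = PS/(PS + CL_efflux) ≤ 1
  for any non-negative efflux.  The interstitial sub-compartment
  concentration is reported as the intracranial ("free BRT") concentration.
* The intracellular:interstitial partition is derived in closed form from
  the total-brain:plasma ratio K_BRT,p at the base parameterization and then
  frozen (see :func:`brain_intracellular_partition`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import (
    CYP_ENZYMES,
    AbsorptionParams,
    ModelParams,
    ParameterError,
    ppsf,
)

UL_MIN_TO_L_H = 6.0e-5  # 1 µL/min = 6e-5 L/h

FLOW_ORGANS = ("lung", "liver", "gut", "spleen", "kidney", "muscle",
               "adipose", "skin", "heart", "bone", "rest")

# state indices
_S = {name: i for i, name in enumerate((
    "sto_solid", "sto_diss", "lumen",
    "venous", "arterial", "lung", "liver", "gut", "spleen", "kidney",
    "muscle", "adipose", "skin", "heart", "bone", "rest",
    "brain_vp", "brain_bc", "brain_is", "brain_ic",
    "cum_hepatic", "cum_renal", "cum_gut_metab",
))}
N_STATES = len(_S)


class SolverFailure(RuntimeError):
    """Integrator did not converge; carries the last valid state."""

    def __init__(self, message: str, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


# ---------------------------------------------------------------------------
# Rodgers–Rowland partitioning
# ---------------------------------------------------------------------------

def kp_rodgers_rowland(compound, physiology, kp_scale: float) -> dict:
    """Tissue:plasma partition coefficients for a moderate-to-strong base.

    Implements the published tissue-composition equations: partitioning into
    tissue water (with Henderson–Hasselbalch ionization at intracellular
    pH 7.0 vs plasma 7.4), electrostatic association of the ionized species
    with acidic phospholipids (association constant estimated from blood-cell
    partitioning), and neutral lipid/phospholipid partitioning of the
    neutral species.  Each Kp is multiplied by ``kp_scale``.
    """
    pka = compound.pka_base_strong
    fup = compound.fu_plasma
    rbp = compound.blood_plasma_ratio
    hct = physiology.hematocrit
    p_ow = 10.0 ** compound.log_p
    p_oil = 10.0 ** (1.115 * compound.log_p - 1.35)  # vegetable-oil logD for adipose
    ph_p = physiology.plasma_ph
    ph_iw = physiology.intracellular_ph

    ion_p = 1.0 + 10.0 ** (pka - ph_p)          # 1 + 10^(pKa−pH,plasma)
    ion_iw = 1.0 + 10.0 ** (pka - ph_iw)

    bc = physiology.blood_cells_composition
    ph_bc = float(bc["ph"])
    ion_bc = 1.0 + 10.0 ** (pka - ph_bc)

    # association constant for acidic phospholipids from blood-cell binding
    kpu_bc = (rbp - (1.0 - hct)) / (hct * fup)
    if kpu_bc <= 0:
        raise ParameterError("blood-cell partition implied by Rbp/hematocrit is non-positive")
    water_term_bc = (ion_bc / ion_p) * float(bc["f_iw"])
    nl_term_bc = (p_ow * float(bc["f_nl"]) + (0.3 * p_ow + 0.7) * float(bc["f_np"])) / ion_p
    ionized_bc = 10.0 ** (pka - ph_bc)
    if ionized_bc > 0:
        ka_ap = ((kpu_bc - water_term_bc - nl_term_bc)
                 * ion_p / (float(bc["ap"]) * ionized_bc))
    else:
        ka_ap = 0.0   # effectively neutral compound: no electrostatic term
    if ka_ap < 0:
        ka_ap = 0.0

    kps: dict[str, float] = {}
    for organ, comp in physiology.tissue_composition.items():
        p_nl = p_oil if organ == "adipose" else p_ow
        water = float(comp["f_ew"]) + (ion_iw / ion_p) * float(comp["f_iw"])
        ap_term = (ka_ap * float(comp["ap"]) * 10.0 ** (pka - ph_iw)) / ion_p
        nl_term = (p_nl * float(comp["f_nl"])
                   + (0.3 * p_nl + 0.7) * float(comp["f_np"])) / ion_p
        kpu = water + ap_term + nl_term
        kps[organ] = kp_scale * fup * kpu
    return kps


# ---------------------------------------------------------------------------
# Absorption
# ---------------------------------------------------------------------------

def dissolution_fraction(t_min: float | np.ndarray, absorption: AbsorptionParams):
    """Weibull fraction dissolved: F(t) = 1 − exp(−ln2·(t/t50)^shape)."""
    t = np.maximum(np.asarray(t_min, dtype=float), 0.0)
    return 1.0 - np.exp(-math.log(2.0) * (t / absorption.weibull_t50) ** absorption.weibull_shape)


def _dissolution_rate_per_h(t_h: float, absorption: AbsorptionParams) -> float:
    """dF/dt in h⁻¹ at time-since-dose t_h (regularized at t→0)."""
    t50_h = absorption.weibull_t50 / 60.0
    s = absorption.weibull_shape
    x = max(t_h, 1.0e-6) / t50_h
    return math.log(2.0) * s / t50_h * x ** (s - 1.0) * math.exp(-math.log(2.0) * x ** s)


def absorption_rate_constant(params: ModelParams) -> float:
    """First-order lumen→gut-tissue rate ka (h⁻¹) from Peff.

    ka = Peff · (2/r) · SEF with Peff in cm/s, intestinal radius r and a
    mucosal surface-amplification factor at segment scale.
    """
    peff_cm_s = params.absorption.effective_permeability * 1.0e-4
    r = params.physiology.intestinal_radius_cm
    return peff_cm_s * 3600.0 * (2.0 / r) * params.physiology.surface_amplification


# ---------------------------------------------------------------------------
# Clearances
# ---------------------------------------------------------------------------

def hepatic_intrinsic_clearance(metabolism, physiology, calibration_factor: float) -> dict:
    """Whole-liver unbound intrinsic clearance per enzyme (L/h).

    CL_enz = CLint(µL/min/pmol) × abundance(pmol) × 6e-5 × calibration_factor.
    """
    return {
        enz: metabolism.cyp_clint[enz] * physiology.liver_enzyme_abundance[enz]
        * UL_MIN_TO_L_H * calibration_factor
        for enz in CYP_ENZYMES
    }


def brain_efflux_clearance(brain_transport, physiology,
                           abcb1_multiplier: float = 1.0,
                           bcrp_multiplier: float = 1.0) -> float:
    """Whole-brain unbound efflux clearance (L/h).

    CLint,u (µL/min/million cells) × brain cell count, with the printed
    transporter concentrations treated as relative-activity anchors
    (multiplier 1.0 at the base values).
    """
    per_cells = (brain_transport.abcb1_clint * abcb1_multiplier
                 + brain_transport.bcrp_clint * bcrp_multiplier)
    return per_cells * physiology.brain_cell_count * UL_MIN_TO_L_H


def brain_intracellular_partition(k_brt_plasma: float, kpuu_base: float,
                                  volumes: dict, kp_bc: float) -> float:
    """Intracellular:interstitial partition consistent with K_BRT,p.

    Solves  (V_vp + V_bc·KpBC + V_is·Kpuu + V_ic·Kic·Kpuu) / V_brain = K_BRT,p
    for Kic at the base steady state, where Kpuu is the unbound
    interstitial:plasma ratio set by passive PS and efflux.
    """
    v_vp, v_bc, v_is, v_ic = (volumes[k] for k in ("vp", "bc", "is", "ic"))
    v_br = v_vp + v_bc + v_is + v_ic
    kic = (k_brt_plasma * v_br - v_vp - v_bc * kp_bc - v_is * kpuu_base) / (v_ic * kpuu_base)
    if kic <= 0:
        raise ParameterError("K_BRT,p constraint yields non-positive intracellular partition")
    return kic


# ---------------------------------------------------------------------------
# Subjects, regimens, model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualSubject:
    """One virtual patient: physiology plus log-normal pathway multipliers."""
    subject_id: int = 0
    body_weight: float = 70.0
    albumin_fold: float = 1.0          # multiplies the patient albumin level
    hematocrit: float = 0.33
    hepatic_clint_mult: float = 1.0
    peff_mult: float = 1.0
    brain_ps_mult: float = 1.0
    abcb1_mult: float = 1.0
    seed_provenance: tuple = ()


MEAN_SUBJECT = VirtualSubject()


@dataclass(frozen=True)
class DoseRegimen:
    dose_amount: float            # mg
    interval: float = 24.0        # h; 24 = OD, 12 = BID
    n_days: int = 14
    route: str = "oral"

    def __post_init__(self):
        if self.dose_amount < 0:
            raise ParameterError("dose must be >= 0")
        if self.interval not in (12.0, 24.0):
            raise ParameterError("interval must be 12 or 24 h")
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")

    def events(self) -> list[tuple[float, float]]:
        n = int(round(self.n_days * 24.0 / self.interval))
        return [(k * self.interval, self.dose_amount) for k in range(n)]

    @property
    def horizon_h(self) -> float:
        return self.n_days * 24.0


@dataclass
class SolverConfig:
    rtol: float = 1.0e-8
    atol: float = 1.0e-10
    method: str = "LSODA"
    output_dt: float = 0.1        # h
    negative_tolerance: float = 1.0e-6  # µmol, hard-error threshold


@dataclass
class SimulationResult:
    """Dense concentration–time output of one regimen simulation."""
    time_h: np.ndarray
    amounts: np.ndarray                 # (n_states, n_times) µmol
    model: "BodyModel"
    regimen: DoseRegimen | None
    dose_times_h: np.ndarray
    total_administered_umol: float

    def _conc(self, state: str, volume: float) -> np.ndarray:
        return self.amounts[_S[state]] / volume

    @property
    def plasma_nmol_l(self) -> np.ndarray:
        """Venous plasma concentration in nmol/L."""
        blood = self._conc("venous", self.model.v_ven)
        return blood / self.model.rbp * 1000.0

    @property
    def brain_interstitial_nmol_l(self) -> np.ndarray:
        """Interstitial sub-compartment concentration (the reported free-BRT)."""
        return self._conc("brain_is", self.model.brain_volumes["is"]) * 1000.0

    @property
    def brain_total_um(self) -> np.ndarray:
        v = self.model.brain_volumes
        a = sum(self.amounts[_S[k]] for k in ("brain_vp", "brain_bc", "brain_is", "brain_ic"))
        return a / (v["vp"] + v["bc"] + v["is"] + v["ic"])

    def compartment_concentrations_um(self) -> dict:
        out = {}
        for name, vol in self.model.state_volumes.items():
            if vol is not None:
                out[name] = self.amounts[_S[name]] / vol
        return out

    @property
    def cumulative_eliminated_umol(self) -> np.ndarray:
        return (self.amounts[_S["cum_hepatic"]] + self.amounts[_S["cum_renal"]]
                + self.amounts[_S["cum_gut_metab"]])

    dose_amounts_umol: np.ndarray = field(default_factory=lambda: np.array([]))

    def mass_balance_error(self) -> float:
        """Max relative deviation of (states + eliminated) from administered."""
        in_body = self.amounts[: _S["cum_hepatic"]].sum(axis=0)
        total = in_body + self.cumulative_eliminated_umol
        if self.total_administered_umol == 0:
            return float(np.max(np.abs(total)))
        expected = np.where(
            self.time_h[None, :] > self.dose_times_h[:, None],
            self.dose_amounts_umol[:, None], 0.0).sum(axis=0)
        mask = expected > 0
        return float(np.max(np.abs(total[mask] - expected[mask]) / expected[mask]))


class BodyModel:
    """Assembled whole-body model for one parameter set and one subject."""

    def __init__(self, params: ModelParams,
                 hepatic_calibration: float = 1.0,
                 brain_ps: float = 16.0,
                 subject: VirtualSubject = MEAN_SUBJECT,
                 ppsf_orientation: str = "literal",
                 kic_override: float | None = None,
                 enzyme_multiplier: Callable[[float], dict] | None = None):
        self.params = params
        self.subject = subject
        self.hepatic_calibration = hepatic_calibration
        self.brain_ps_base = brain_ps
        self.ppsf_orientation = ppsf_orientation
        self.enzyme_multiplier = enzyme_multiplier

        c, ph = params.compound, params.physiology
        self.rbp = c.blood_plasma_ratio
        self.mw = c.molecular_weight

        # effective unbound fraction in the (possibly albumin-shifted) patient
        self.fu_eff = c.fu_plasma * ppsf(
            c.fu_plasma,
            ph.albumin_patient * subject.albumin_fold,
            ph.albumin_healthy_reference,
            orientation=ppsf_orientation,
        )

        # partition coefficients (Kp frozen at the in-vitro fup)
        self.kp = kp_rodgers_rowland(c, ph, params.distribution.kp_scale)

        # flows scaled to the subject (weight-ratio scaling of volumes/flows)
        scale = subject.body_weight / ph.body_weight
        self.q = {k: v for k, v in ph.organ_flows.items()}
        self.v = {k: v * scale for k, v in ph.organ_volumes.items()}
        self.v_ven = ph.venous_volume * scale
        self.v_art = ph.arterial_volume * scale

        hct = subject.hematocrit
        self.kp_bc = (self.rbp - (1.0 - hct)) / hct
        v_br = self.v["brain"]
        v_vasc = v_br * ph.brain_vascular_fraction
        self.brain_volumes = {
            "vp": v_vasc * (1.0 - hct),
            "bc": v_vasc * hct,
            "is": v_br * ph.brain_interstitial_fraction,
            "ic": v_br * (1.0 - ph.brain_vascular_fraction - ph.brain_interstitial_fraction),
        }
        self.q_brain = ph.organ_flows["brain"]

        # clearances
        self.cl_enz = hepatic_intrinsic_clearance(
            params.metabolism, ph, hepatic_calibration * subject.hepatic_clint_mult)
        self.cl_gut_3a4 = (params.metabolism.cyp_clint["CYP3A4"] * ph.intestinal_cyp3a4
                           * UL_MIN_TO_L_H * hepatic_calibration * subject.hepatic_clint_mult)
        self.cl_renal = params.metabolism.gfr * 0.06 * self.fu_eff  # mL/min→L/h × fu
        self.cl_efflux = brain_efflux_clearance(
            params.brain_transport, ph, abcb1_multiplier=subject.abcb1_mult)
        self.brain_ps = brain_ps * subject.brain_ps_mult
        self.brain_ps_cell = 5000.0   # interstitial↔intracellular, fast (L/h, unbound basis)
        self.ps_bc = 50.0             # vascular plasma↔blood cells, fast (L/h)

        # Kp,uu and the frozen intracellular partition
        self.kpuu = self.brain_ps / (self.brain_ps + self.cl_efflux) \
            if (self.brain_ps + self.cl_efflux) > 0 else 1.0
        if kic_override is not None:
            self.kic = kic_override
        else:
            kpuu_base = brain_ps / (brain_ps + brain_efflux_clearance(params.brain_transport, ph))
            self.kic = brain_intracellular_partition(
                params.distribution.k_brt_plasma, kpuu_base, self.brain_volumes, self.kp_bc)

        self.ka = absorption_rate_constant(params) * subject.peff_mult
        self.ke_gastric = 60.0 / params.absorption.gastric_emptying_time  # h⁻¹

        self.state_volumes = {
            "sto_solid": None, "sto_diss": None, "lumen": None,
            "venous": self.v_ven, "arterial": self.v_art,
            **{o: self.v[o] for o in FLOW_ORGANS if o != "liver"},
            "liver": self.v["liver"],
            "brain_vp": self.brain_volumes["vp"], "brain_bc": self.brain_volumes["bc"],
            "brain_is": self.brain_volumes["is"], "brain_ic": self.brain_volumes["ic"],
            "cum_hepatic": None, "cum_renal": None, "cum_gut_metab": None,
        }

    # -- fluxes ------------------------------------------------------------

    def brain_exchange_fluxes(self, c_vp: float, c_bc: float, c_is: float,
                              c_ic: float) -> dict:
        """Net fluxes (µmol/h) between the four brain sub-compartments.

        Passive BBB flux PS·fu·(C_vp − C_is); unidirectional efflux
        CL_e·fu·C_is back to vascular plasma; cellular exchange
        PS_cell·fu·(C_is − C_ic/Kic).
        """
        fu = self.fu_eff
        passive = self.brain_ps * fu * (c_vp - c_is)
        efflux = self.cl_efflux * fu * c_is
        cellular = self.brain_ps_cell * fu * (c_is - c_ic / self.kic)
        bc_exchange = self.ps_bc * (c_vp * self.kp_bc - c_bc)
        return {
            "vascular_plasma": -passive + efflux - bc_exchange,
            "blood_cells": bc_exchange,
            "interstitial": passive - efflux - cellular,
            "intracellular": cellular,
        }

    def _enzyme_mults(self, t: float) -> dict:
        if self.enzyme_multiplier is None:
            return {}
        return self.enzyme_multiplier(t)

    def rhs(self, t: float, y: np.ndarray, dose_time: float, dose_umol: float) -> np.ndarray:
        p = self.params
        dy = np.zeros(N_STATES)
        q, v, kp, rbp, fu = self.q, self.v, self.kp, self.rbp, self.fu_eff

        # absorption chain
        u = dose_umol * _dissolution_rate_per_h(t - dose_time, p.absorption) \
            if dose_umol > 0 else 0.0
        dy[_S["sto_solid"]] = -u
        dy[_S["sto_diss"]] = u - self.ke_gastric * y[_S["sto_diss"]]
        dy[_S["lumen"]] = self.ke_gastric * y[_S["sto_diss"]] - self.ka * y[_S["lumen"]]

        c_art = y[_S["arterial"]] / self.v_art       # blood µM
        c_ven = y[_S["venous"]] / self.v_ven

        def c_out(organ: str) -> float:
            return (y[_S[organ]] / v[organ]) * rbp / kp[organ]

        mults = self._enzyme_mults(t)
        m3a4 = mults.get("CYP3A4", 1.0)

        # lung: venous → lung → arterial
        dy[_S["lung"]] = q["lung"] * (c_ven - c_out("lung"))
        dy[_S["arterial"]] = q["lung"] * c_out("lung") - sum(
            q[o] for o in ("liver", "gut", "spleen", "kidney", "muscle", "adipose",
                           "skin", "heart", "bone", "rest")) * c_art \
            - self.q_brain * c_art

        venous_in = 0.0
        for organ in ("muscle", "adipose", "skin", "heart", "bone", "rest"):
            out = c_out(organ)
            dy[_S[organ]] = q[organ] * (c_art - out)
            venous_in += q[organ] * out

        # kidney with renal filtration of arterial plasma
        out_k = c_out("kidney")
        renal_flux = self.cl_renal * c_art / rbp
        dy[_S["kidney"]] = q["kidney"] * (c_art - out_k) - renal_flux
        dy[_S["cum_renal"]] = renal_flux
        venous_in += q["kidney"] * out_k

        # spleen and gut drain to the liver (portal)
        out_sp = c_out("spleen")
        dy[_S["spleen"]] = q["spleen"] * (c_art - out_sp)
        out_gut = c_out("gut")
        gut_unbound = fu * (y[_S["gut"]] / v["gut"]) / kp["gut"]
        gut_metab = self.cl_gut_3a4 * m3a4 * gut_unbound
        dy[_S["gut"]] = (q["gut"] * (c_art - out_gut)
                         + self.ka * y[_S["lumen"]] - gut_metab)
        dy[_S["cum_gut_metab"]] = gut_metab

        # liver: hepatic artery + portal inflow, enzyme elimination
        q_hv = q["liver"] + q["gut"] + q["spleen"]
        out_liv = (y[_S["liver"]] / v["liver"]) * rbp / kp["liver"]
        liv_unbound = fu * (y[_S["liver"]] / v["liver"]) / kp["liver"]
        hep_metab = sum(cl * mults.get(enz, 1.0) for enz, cl in self.cl_enz.items()) \
            * liv_unbound
        dy[_S["liver"]] = (q["liver"] * c_art + q["gut"] * out_gut
                           + q["spleen"] * out_sp - q_hv * out_liv - hep_metab)
        dy[_S["cum_hepatic"]] = hep_metab
        venous_in += q_hv * out_liv

        # brain: four sub-compartments
        bv = self.brain_volumes
        c_vp = y[_S["brain_vp"]] / bv["vp"]
        c_bc = y[_S["brain_bc"]] / bv["bc"]
        c_is = y[_S["brain_is"]] / bv["is"]
        c_ic = y[_S["brain_ic"]] / bv["ic"]
        fluxes = self.brain_exchange_fluxes(c_vp, c_bc, c_is, c_ic)
        hct = self.subject.hematocrit
        q_pl = self.q_brain * (1.0 - hct)
        q_bc = self.q_brain * hct
        c_art_pl = c_art / rbp
        dy[_S["brain_vp"]] = q_pl * (c_art_pl - c_vp) + fluxes["vascular_plasma"]
        dy[_S["brain_bc"]] = q_bc * (c_art_pl * self.kp_bc - c_bc) + fluxes["blood_cells"]
        dy[_S["brain_is"]] = fluxes["interstitial"]
        dy[_S["brain_ic"]] = fluxes["intracellular"]
        brain_out = q_pl * c_vp + q_bc * c_bc
        venous_in += brain_out

        dy[_S["venous"]] = venous_in - q["lung"] * c_ven
        return dy


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def simulate_events(model: BodyModel, events: Sequence[tuple[float, float]],
                    t_end: float, solver: SolverConfig | None = None,
                    output_times: np.ndarray | None = None) -> SimulationResult:
    """Integrate the model over a list of (time_h, dose_mg) oral dose events."""
    solver = solver or SolverConfig()
    events = sorted(events, key=lambda e: e[0])
    dose_times = [t for t, _ in events]
    breakpoints = sorted(set([0.0] + dose_times + [t_end]))
    breakpoints = [b for b in breakpoints if b <= t_end]
    if breakpoints[-1] < t_end:
        breakpoints.append(t_end)

    if output_times is None:
        output_times = np.arange(0.0, t_end + 1.0e-9, solver.output_dt)
    output_times = np.asarray(output_times, dtype=float)

    y = np.zeros(N_STATES)
    times_out = [np.array([0.0])]
    states_out = [y.reshape(-1, 1).copy()]
    total_umol = 0.0
    dose_lookup = dict()
    for t, mg in events:
        dose_lookup[t] = dose_lookup.get(t, 0.0) + mg / model.mw * 1000.0

    current_dose_time, current_dose_umol = 0.0, 0.0
    for i in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[i], breakpoints[i + 1]
        if t0 in dose_lookup:
            amount = dose_lookup[t0]
            y[_S["sto_solid"]] += amount
            total_umol += amount
            current_dose_time, current_dose_umol = t0, amount
        if t1 <= t0:
            continue
        t_eval = output_times[(output_times > t0) & (output_times <= t1)]
        t_eval = np.unique(np.concatenate([t_eval, [t1]]))
        sol = solve_ivp(
            model.rhs, (t0, t1), y, method=solver.method,
            t_eval=t_eval, rtol=solver.rtol, atol=solver.atol,
            args=(current_dose_time, current_dose_umol),
            max_step=max((t1 - t0) / 4.0, 0.5),
        )
        if not sol.success:
            raise SolverFailure(f"integration failed on [{t0}, {t1}]: {sol.message}",
                                last_state=y, last_time=t0)
        if sol.y.min() < -solver.negative_tolerance:
            raise SolverFailure("state went negative beyond tolerance",
                                last_state=sol.y[:, -1], last_time=sol.t[-1])
        times_out.append(sol.t)
        states_out.append(sol.y)
        y = sol.y[:, -1].copy()

    time = np.concatenate(times_out)
    amounts = np.concatenate(states_out, axis=1)
    keep = np.concatenate([[True], np.diff(time) > 0])
    unique_times = sorted(dose_lookup)
    return SimulationResult(
        time_h=time[keep], amounts=np.clip(amounts[:, keep], 0.0, None),
        model=model, regimen=None,
        dose_times_h=np.array(unique_times), total_administered_umol=total_umol,
        dose_amounts_umol=np.array([dose_lookup[t] for t in unique_times]),
    )


def simulate_regimen(model: BodyModel, regimen: DoseRegimen,
                     solver: SolverConfig | None = None) -> SimulationResult:
    """Simulate a repeated oral regimen; troughs land exactly on pre-dose times."""
    result = simulate_events(model, regimen.events(), regimen.horizon_h, solver=solver)
    result.regimen = regimen
    return result


def build_model(params: ModelParams, hepatic_calibration: float, brain_ps: float,
                subject: VirtualSubject = MEAN_SUBJECT, **kwargs) -> BodyModel:
    return BodyModel(params, hepatic_calibration=hepatic_calibration,
                     brain_ps=brain_ps, subject=subject, **kwargs)


def subject_with(subject: VirtualSubject, **kwargs) -> VirtualSubject:
    return replace(subject, **kwargs)
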