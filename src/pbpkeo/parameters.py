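"""Typed parameter records for the osimertinib PBPK-EO model.

Every drug-specific, binding-kinetic and physiological constant used by the
simulator lives in one of the dataclasses below, loaded from the packaged
declarative fixture (``data/table1.yaml``).  The small closed-form estimators
that turn assay observables into model inputs are also here:

* :func:`unionized_fraction` — Henderson–Hasselbalch unionized fraction of a
  monoprotic base,
* :func:`transporter_clint_from_assay` — intrinsic efflux clearance from a
  bidirectional transwell assay,
* :func:`ppsf` — plasma-protein scale factor mapping an albumin change onto
  the fraction unbound,
* :func:`kdeg_from_halflife` — first-order turnover constant from a
  protein half-life.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml

EGFR_VARIANTS = ("wild_type", "t790m_l858r", "l858r", "c797s")
CYP_ENZYMES = ("CYP1A2", "CYP2A6", "CYP2C9", "CYP2E1", "CYP3A4", "CYP3A5")

MOLECULAR_WEIGHT_OSI = 499.6  # g/mol; nmol/L <-> uM conversions route through this


def nmol_per_l_to_um(c_nmol_l: float) -> float:
    """nmol/L to µM (numerically /1000; kept explicit for auditability)."""
    return c_nmol_l / 1000.0


def um_to_nmol_per_l(c_um: float) -> float:
    return c_um * 1000.0


def mg_to_umol(mg: float, molecular_weight: float = MOLECULAR_WEIGHT_OSI) -> float:
    return mg / molecular_weight * 1000.0


class ParameterError(ValueError):
    """Raised when a parameter record violates its invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundParams:
    molecular_weight: float      # g/mol
    pka_base_strong: float
    pka_base_weak: float
    log_p: float
    solubility_water: float      # mg/mL
    fu_plasma: float             # fraction unbound (fup)
    blood_plasma_ratio: float    # Rbp

    def __post_init__(self):
        if not (0.0 < self.fu_plasma <= 1.0):
            raise ParameterError(f"fu_plasma must be in (0,1]: {self.fu_plasma}")
        if self.blood_plasma_ratio <= 0:
            raise ParameterError("blood_plasma_ratio must be > 0")
        if self.solubility_water <= 0:
            raise ParameterError("solubility must be > 0")


@dataclass(frozen=True)
class AbsorptionParams:
    gastric_emptying_time: float   # min, mean first-order gastric residence
    effective_permeability: float  # 1e-4 cm/s
    weibull_t50: float             # min
    weibull_shape: float

    def __post_init__(self):
        for name in ("gastric_emptying_time", "effective_permeability",
                     "weibull_t50", "weibull_shape"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.weibull_shape > 5:
            raise ParameterError("weibull_shape must lie in (0, 5]")


@dataclass(frozen=True)
class DistributionParams:
    kp_scale: float
    k_brt_plasma: float            # total brain : plasma partition
    partition_method: Literal["rodgers_rowland"] = "rodgers_rowland"

    def __post_init__(self):
        if self.kp_scale <= 0 or self.k_brt_plasma <= 0:
            raise ParameterError("kp_scale and k_brt_plasma must be > 0")


@dataclass(frozen=True)
class MetabolismParams:
    cyp_clint: dict                     # enzyme -> µL/min/pmol
    gfr: float                          # mL/min
    renal_clearance_rule: Literal["gfr_times_fup"] = "gfr_times_fup"

    def __post_init__(self):
        missing = set(CYP_ENZYMES) - set(self.cyp_clint)
        if missing:
            raise ParameterError(f"missing CYP enzymes: {sorted(missing)}")
        if any(v < 0 for v in self.cyp_clint.values()):
            raise ParameterError("CYP CLint values must be >= 0")


@dataclass(frozen=True)
class BrainTransportParams:
    abcb1_clint: float        # µL/min/million-cells
    bcrp_clint: float         # µL/min/million-cells
    abcb1_conc: float         # µM, relative-activity anchor
    bcrp_conc: float          # µM
    passive_ps_bbb: float     # L/h, set by calibration

    def __post_init__(self):
        if min(self.abcb1_clint, self.bcrp_clint, self.abcb1_conc,
               self.bcrp_conc, self.passive_ps_bbb) < 0:
            raise ParameterError("brain transport parameters must be >= 0")


@dataclass(frozen=True)
class TransportAssayRecord:
    papp_ab: float             # 1e-6 cm/s, apical->basolateral
    net_efflux_ratio: float    # NFR
    filter_surface_area: float # cm^2
    cell_count: float          # million cells
    assay_ph: float
    unionized_fraction: float  # gamma at assay pH

    def __post_init__(self):
        if self.net_efflux_ratio < 1:
            raise ParameterError("net efflux ratio < 1: negative efflux is not a valid assay")
        if not (0.0 < self.unionized_fraction <= 1.0):
            raise ParameterError("unionized_fraction must be in (0,1]")


@dataclass(frozen=True)
class EOParams:
    kon: dict                       # variant -> µM^-1 per time-base unit
    koff: float                     # h^-1
    egfr_t0: float                  # µM
    kdeg: float                     # h^-1
    kon_time_base: Literal["per_hour", "per_second"] = "per_hour"

    def __post_init__(self):
        missing = set(EGFR_VARIANTS) - set(self.kon)
        if missing:
            raise ParameterError(f"missing EGFR variants: {sorted(missing)}")
        if any(v < 0 for v in self.kon.values()) or self.koff < 0:
            raise ParameterError("rate constants must be >= 0")
        if self.egfr_t0 <= 0 or self.kdeg <= 0:
            raise ParameterError("egfr_t0 and kdeg must be > 0")

    def kon_per_hour(self, variant: str) -> float:
        """kon resolved to µM⁻¹·h⁻¹ under the configured time base."""
        k = self.kon[variant]
        return k * 3600.0 if self.kon_time_base == "per_second" else k


@dataclass(frozen=True)
class CompoundInteractionParams:
    ki_cyp3a: float
    ki_abcb1: float
    ki_bcrp: float
    ec50_cyp3a4: float
    emax_cyp3a4: float

    def __post_init__(self):
        if min(self.ki_cyp3a, self.ki_abcb1, self.ki_bcrp,
               self.ec50_cyp3a4, self.emax_cyp3a4) <= 0:
            raise ParameterError("interaction parameters must be > 0")


@dataclass(frozen=True)
class PhysiologyParams:
    hematocrit: float
    albumin_patient: float            # g/dL as printed; used through ratios only
    albumin_healthy_reference: float
    body_weight: float                # kg
    organ_volumes: dict               # organ -> L
    organ_flows: dict                 # organ -> L/h blood flow
    venous_volume: float
    arterial_volume: float
    brain_vascular_fraction: float
    brain_interstitial_fraction: float
    liver_enzyme_abundance: dict      # enzyme -> pmol whole liver
    intestinal_cyp3a4: float          # pmol whole intestine
    brain_cell_count: float           # million cells
    tissue_composition: dict
    blood_cells_composition: dict
    plasma_water_fraction: float
    intracellular_ph: float
    plasma_ph: float
    intestinal_radius_cm: float
    surface_amplification: float

    def __post_init__(self):
        if not (0.0 < self.hematocrit < 1.0):
            raise ParameterError("hematocrit must be in (0,1)")
        if self.albumin_patient <= 0 or self.albumin_healthy_reference <= 0:
            raise ParameterError("albumin values must be > 0")
        for d in (self.organ_volumes, self.organ_flows):
            if any(v <= 0 for v in d.values()):
                raise ParameterError("organ volumes and flows must be > 0")


@dataclass
class ModelParams:
    """Aggregate of every record the simulator needs."""
    compound: CompoundParams
    absorption: AbsorptionParams
    distribution: DistributionParams
    metabolism: MetabolismParams
    brain_transport: BrainTransportParams
    eo: EOParams
    interactions: CompoundInteractionParams
    physiology: PhysiologyParams
    assay: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Closed-form operations
# ---------------------------------------------------------------------------

def unionized_fraction(pka: float, ph: float) -> float:
    """Fraction of a monoprotic base in the unionized form at a given pH.

    log10(unionized/ionized) = pH − pKa, hence γ = u/(1+u) with
    u = 10**(pH − pKa).  Strictly increasing in pH; → 1 as pKa → −∞.
    """
    exponent = ph - pka
    if exponent > 300.0:      # fully unionized limit; avoid float overflow
        return 1.0
    u = 10.0 ** exponent
    return u / (1.0 + u)


def transporter_clint_from_assay(assay: TransportAssayRecord) -> float:
    """Intrinsic efflux clearance (µL/min/million-cells) from a transwell assay.

    CLint,u = 2·Papp,A→B·(NFR − 1)·SA / (γ·cells).  Papp is in 1e-6 cm/s and
    the result is returned per million cells; the 0.06 factor converts
    1e-6 cm³/s to µL/min.
    """
    numerator_ul_min = (2.0 * assay.papp_ab * (assay.net_efflux_ratio - 1.0)
                        * assay.filter_surface_area) * 0.06
    return numerator_ul_min / (assay.unionized_fraction * assay.cell_count)


def implied_assay_cell_count(papp_ab: float, nfr: float, surface_area: float,
                             gamma: float, target_clint: float) -> float:
    """Back-calculate the transwell cell count (million cells) that makes the
    assay reproduce a stated CLint,u.  The filter cell count is not published;
    this records the implied value rather than asserting it."""
    numerator_ul_min = 2.0 * papp_ab * (nfr - 1.0) * surface_area * 0.06
    return numerator_ul_min / (gamma * target_clint)


def ppsf(fu_plasma: float, albumin_patient: float, albumin_healthy: float,
         orientation: Literal["physiological", "literal"] = "physiological",
         ) -> float:
    """Plasma-protein scale factor: PPSF = 1/(fup + (1 − fup)·albumin_f).

    The scaled fraction unbound is ``fu_plasma * ppsf(...)``.

    orientation
        ``"physiological"`` (default): albumin_f = patient/healthy, so
        hypoalbuminemia raises the unbound fraction — the standard
        binding-dilution relation fu2 = 1/(1 + (alb2/alb1)(1−fu1)/fu1).
        ``"literal"``: albumin_f = healthy/patient, the alternative
        orientation in which the unbound fraction falls with falling albumin;
        kept selectable because the published factor-sweep behaviour follows
        this direction (see the methods note).
    """
    if not (0.0 < fu_plasma <= 1.0):
        raise ParameterError("fu_plasma must be in (0,1]")
    if albumin_patient <= 0 or albumin_healthy <= 0:
        raise ParameterError("albumin values must be > 0")
    if orientation == "physiological":
        albumin_f = albumin_patient / albumin_healthy
    else:
        albumin_f = albumin_healthy / albumin_patient
    scale = 1.0 / (fu_plasma + (1.0 - fu_plasma) * albumin_f)
    if fu_plasma * scale > 1.0:
        warnings.warn("scaled fraction unbound exceeded 1; clamped",
                      RuntimeWarning, stacklevel=2)
        scale = 1.0 / fu_plasma
    return scale


def kdeg_from_halflife(halflife_h: float) -> float:
    """First-order degradation rate constant ln2 / t½ (h⁻¹)."""
    if halflife_h <= 0:
        raise ParameterError("halflife must be > 0")
    return math.log(2.0) / halflife_h


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("pbpkeo").joinpath("data", name)))


def _val(node) -> float:
    return float(node["value"]) if isinstance(node, dict) else float(node)


def load_params(table1_path: str | Path | None = None,
                physiology_path: str | Path | None = None) -> ModelParams:
    """Load the packaged default parameterization (or explicit YAML files)."""
    t1_path = Path(table1_path) if table1_path else _data_path("table1.yaml")
    ph_path = Path(physiology_path) if physiology_path else _data_path("physiology_standard.yaml")
    t1 = yaml.safe_load(t1_path.read_text())
    ph = yaml.safe_load(ph_path.read_text())

    compound = CompoundParams(
        molecular_weight=_val(t1["compound"]["molecular_weight"]),
        pka_base_strong=_val(t1["compound"]["pka_base_strong"]),
        pka_base_weak=_val(t1["compound"]["pka_base_weak"]),
        log_p=_val(t1["compound"]["log_p"]),
        solubility_water=_val(t1["compound"]["solubility_water"]),
        fu_plasma=_val(t1["compound"]["fu_plasma"]),
        blood_plasma_ratio=_val(t1["compound"]["blood_plasma_ratio"]),
    )
    absorption = AbsorptionParams(
        gastric_emptying_time=_val(t1["absorption"]["gastric_emptying_time"]),
        effective_permeability=_val(t1["absorption"]["effective_permeability"]),
        weibull_t50=_val(t1["absorption"]["weibull_t50"]),
        weibull_shape=_val(t1["absorption"]["weibull_shape"]),
    )
    distribution = DistributionParams(
        kp_scale=_val(t1["distribution"]["kp_scale"]),
        k_brt_plasma=_val(t1["distribution"]["k_brt_plasma"]),
        partition_method=t1["distribution"]["partition_method"],
    )
    metabolism = MetabolismParams(
        cyp_clint={k: _val(v) for k, v in t1["metabolism"]["cyp_clint"].items()},
        gfr=_val(t1["metabolism"]["gfr"]),
        renal_clearance_rule=t1["metabolism"]["renal_clearance_rule"],
    )
    brain_transport = BrainTransportParams(
        abcb1_clint=_val(t1["brain_transport"]["abcb1_clint"]),
        bcrp_clint=_val(t1["brain_transport"]["bcrp_clint"]),
        abcb1_conc=_val(t1["brain_transport"]["abcb1_conc"]),
        bcrp_conc=_val(t1["brain_transport"]["bcrp_conc"]),
        passive_ps_bbb=0.0,  # calibrated; filled by BodyModel/locked config
    )
    eo = EOParams(
        kon={k: _val(v) for k, v in t1["eo"]["kon"].items()},
        koff=_val(t1["eo"]["koff"]),
        egfr_t0=_val(t1["eo"]["egfr_t0"]),
        kdeg=kdeg_from_halflife(_val(t1["eo"]["egfr_halflife"])),
        kon_time_base=t1["eo"].get("kon_time_base", "per_hour"),
    )
    interactions = CompoundInteractionParams(
        ki_cyp3a=_val(t1["interactions"]["ki_cyp3a"]),
        ki_abcb1=_val(t1["interactions"]["ki_abcb1"]),
        ki_bcrp=_val(t1["interactions"]["ki_bcrp"]),
        ec50_cyp3a4=_val(t1["interactions"]["ec50_cyp3a4"]),
        emax_cyp3a4=_val(t1["interactions"]["emax_cyp3a4"]),
    )
    mppgl = _val(ph["liver_enzymes"]["mppgl"])
    liver_g = _val(ph["liver_enzymes"]["liver_weight"])
    abundance = {
        enz: float(a) * mppgl * liver_g
        for enz, a in ph["liver_enzymes"]["abundance_pmol_per_mg"].items()
    }
    physiology = PhysiologyParams(
        hematocrit=_val(t1["physiology_disease"]["hematocrit"]),
        albumin_patient=_val(t1["physiology_disease"]["albumin_patient"]),
        albumin_healthy_reference=_val(t1["physiology_disease"]["albumin_healthy_reference"]),
        body_weight=_val(ph["body_weight"]),
        organ_volumes={k: float(v["volume"]) for k, v in ph["organs"].items()},
        organ_flows={k: float(v["flow"]) for k, v in ph["organs"].items()},
        venous_volume=_val(ph["blood"]["venous_volume"]),
        arterial_volume=_val(ph["blood"]["arterial_volume"]),
        brain_vascular_fraction=float(ph["brain_subcompartments"]["vascular_blood_fraction"]),
        brain_interstitial_fraction=float(ph["brain_subcompartments"]["interstitial_fraction"]),
        liver_enzyme_abundance=abundance,
        intestinal_cyp3a4=float(ph["intestinal_cyp3a4_total_pmol"]),
        brain_cell_count=_val(ph["brain_cell_count"]),
        tissue_composition=ph["tissue_composition"],
        blood_cells_composition=ph["blood_cells_composition"],
        plasma_water_fraction=float(ph["plasma_water_fraction"]),
        intracellular_ph=float(ph["intracellular_ph"]),
        plasma_ph=float(ph["plasma_ph"]),
        intestinal_radius_cm=float(ph["absorption_geometry"]["intestinal_radius_cm"]),
        surface_amplification=float(ph["absorption_geometry"]["surface_amplification"]),
    )
    return ModelParams(
        compound=compound, absorption=absorption, distribution=distribution,
        metabolism=metabolism, brain_transport=brain_transport, eo=eo,
        interactions=interactions, physiology=physiology,
        assay=t1.get("transport_assay", {}),
    )
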