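"""Whole-body PBPK core: partitioning, absorption, clearances, simulation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pbpkeo.analysis import standard_model, summarize_pk
from pbpkeo.parameters import CompoundParams, load_params
from pbpkeo.pbpk import (
    MEAN_SUBJECT,
    BodyModel,
    DoseRegimen,
    absorption_rate_constant,
    brain_efflux_clearance,
    dissolution_fraction,
    hepatic_intrinsic_clearance,
    kp_rodgers_rowland,
    simulate_regimen,
)


def rodgers_rowland_reference(compound, physiology, kp_scale):
    """Independent literal transcription of the published moderate-to-strong
    base partition equations, used as a dual-implementation oracle."""
    pka, fup, rbp = compound.pka_base_strong, compound.fu_plasma, compound.blood_plasma_ratio
    hct = physiology.hematocrit
    p = 10.0 ** compound.log_p
    bc = physiology.blood_cells_composition
    x = lambda ph: 10.0 ** (pka - ph)
    kpu_bc = (rbp - (1 - hct)) / (hct * fup)
    ka_ap = ((kpu_bc - (1 + x(bc["ph"])) / (1 + x(7.4)) * bc["f_iw"]
              - (p * bc["f_nl"] + (0.3 * p + 0.7) * bc["f_np"]) / (1 + x(7.4)))
             * (1 + x(7.4)) / (bc["ap"] * x(bc["ph"])))
    out = {}
    for organ, c in physiology.tissue_composition.items():
        pn = 10.0 ** (1.115 * compound.log_p - 1.35) if organ == "adipose" else p
        kpu = (c["f_ew"] + (1 + x(7.0)) / (1 + x(7.4)) * c["f_iw"]
               + ka_ap * c["ap"] * x(7.0) / (1 + x(7.4))
               + (pn * c["f_nl"] + (0.3 * pn + 0.7) * c["f_np"]) / (1 + x(7.4)))
        out[organ] = kp_scale * fup * kpu
    return out


class TestRodgersRowland:
    def test_kp_scale_is_exactly_multiplicative(self, params):
        kp1 = kp_rodgers_rowland(params.compound, params.physiology, 1.0)
        kp15 = kp_rodgers_rowland(params.compound, params.physiology, 1.5)
        for organ in kp1:
            assert kp15[organ] == pytest.approx(1.5 * kp1[organ], rel=1e-12)

    def test_matches_independent_transcription(self, params):
        ours = kp_rodgers_rowland(params.compound, params.physiology, 1.5)
        ref = rodgers_rowland_reference(params.compound, params.physiology, 1.5)
        for organ in ours:
            assert ours[organ] == pytest.approx(ref[organ], rel=1e-9)

    def test_no_lipophilicity_no_binding_limit_is_tissue_water(self, params):
        """A neutral, non-binding, water-like compound partitions into tissue
        water only."""
        watery = CompoundParams(molecular_weight=100.0, pka_base_strong=-1000.0,
                                pka_base_weak=-1000.0, log_p=-10.0,
                                solubility_water=10.0, fu_plasma=1.0,
                                blood_plasma_ratio=1.0)
        kp = kp_rodgers_rowland(watery, params.physiology, 1.0)
        for organ, c in params.physiology.tissue_composition.items():
            # neutral phospholipid counts as 70 % water-equivalent in the
            # published equations, hence the 0.7·f_np residual
            water = c["f_ew"] + c["f_iw"] + 0.7 * c["f_np"]
            assert kp[organ] == pytest.approx(water, rel=1e-6)


class TestDissolution:
    def test_anchor_points_and_monotonicity(self, params):
        a = params.absorption
        t = np.linspace(0.0, 240.0, 400)
        f = dissolution_fraction(t, a)
        assert f[0] == 0.0
        assert dissolution_fraction(15.0, a) == pytest.approx(0.5, rel=1e-12)
        assert np.all(np.diff(f) >= 0)

    def test_closed_form_at_60min(self, params):
        a = params.absorption
        expected = 1.0 - math.exp(-math.log(2.0) * (60.0 / 15.0) ** 0.92)
        assert dissolution_fraction(60.0, a) == pytest.approx(expected, rel=1e-12)


class TestClearances:
    def test_zero_abundance_gives_zero(self, params):
        phys = replace(params.physiology, liver_enzyme_abundance={
            e: 0.0 for e in params.physiology.liver_enzyme_abundance})
        cl = hepatic_intrinsic_clearance(params.metabolism, phys, 1.0)
        assert sum(cl.values()) == 0.0

    def test_calibration_factor_linearity(self, params):
        cl1 = hepatic_intrinsic_clearance(params.metabolism, params.physiology, 1.0)
        cl2 = hepatic_intrinsic_clearance(params.metabolism, params.physiology, 2.0)
        for enz in cl1:
            assert cl2[enz] == pytest.approx(2.0 * cl1[enz])

    def test_efflux_multiplier_scaling(self, params):
        base = brain_efflux_clearance(params.brain_transport, params.physiology)
        no_efflux = brain_efflux_clearance(params.brain_transport, params.physiology,
                                           abcb1_multiplier=0.0, bcrp_multiplier=0.0)
        assert no_efflux == 0.0
        assert base > 0


class TestBrainExchange:
    def test_kpuu_limits(self, params):
        model = BodyModel(params, hepatic_calibration=2.15, brain_ps=13.7)
        assert 0.0 < model.kpuu <= 1.0
        no_efflux = BodyModel(params, hepatic_calibration=2.15, brain_ps=13.7,
                              subject=replace(MEAN_SUBJECT, abcb1_mult=0.0),
                              kic_override=model.kic)
        # BCRP still present, so Kp,uu rises but stays ≤ 1
        assert no_efflux.kpuu > model.kpuu
        assert no_efflux.kpuu <= 1.0

    def test_fluxes_vanish_at_equilibrium(self, params):
        model = BodyModel(params, hepatic_calibration=2.15, brain_ps=13.7,
                          subject=replace(MEAN_SUBJECT, abcb1_mult=0.0))
        model.cl_efflux = 0.0
        f = model.brain_exchange_fluxes(1.0, model.kp_bc, 1.0, model.kic)
        for v in f.values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_strong_efflux_empties_interstitial(self, params):
        model = BodyModel(params, hepatic_calibration=2.15, brain_ps=13.7,
                          subject=replace(MEAN_SUBJECT, abcb1_mult=1e6),
                          kic_override=1.0)
        assert model.kpuu < 1e-3


class TestSimulation:
    def test_zero_dose_all_zero(self, params, calibration):
        model = standard_model(params, calibration=calibration)
        res = simulate_regimen(model, DoseRegimen(0.0, 24.0, 2))
        assert np.all(res.amounts == 0.0)

    def test_dose_proportionality(self, params, calibration, base_result_80mg):
        model = standard_model(params, calibration=calibration)
        res160 = simulate_regimen(model, DoseRegimen(160.0, 24.0, 14))
        auc80 = summarize_pk(base_result_80mg, 24.0).auc_nmol_h_l
        auc160 = summarize_pk(res160, 24.0).auc_nmol_h_l
        assert auc160 / auc80 == pytest.approx(2.0, rel=1e-6)

    def test_mass_balance_and_nonnegativity(self, base_result_80mg):
        assert base_result_80mg.mass_balance_error() < 1e-6
        assert base_result_80mg.amounts.min() >= 0.0

    def test_periodic_steady_state_by_day14(self, base_result_80mg):
        pk = summarize_pk(base_result_80mg, 24.0)
        assert pk.steady_state  # |Ctrough(d14) − Ctrough(d13)| / Ctrough < 1 %

    def test_trough_sampled_exactly_at_predose(self, base_result_80mg):
        assert base_result_80mg.time_h[-1] == pytest.approx(336.0)

    def test_absorption_rate_from_peff(self, params):
        ka = absorption_rate_constant(params)
        peff = params.absorption.effective_permeability * 1e-4
        expected = peff * 3600 * (2 / params.physiology.intestinal_radius_cm) \
            * params.physiology.surface_amplification
        assert ka == pytest.approx(expected)
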