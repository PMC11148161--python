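"""Closed-form parameter estimators and fixture round-trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkeo.parameters import (
    ParameterError,
    TransportAssayRecord,
    implied_assay_cell_count,
    kdeg_from_halflife,
    load_params,
    ppsf,
    transporter_clint_from_assay,
    unionized_fraction,
)


class TestUnionizedFraction:
    @pytest.mark.parametrize("pka, ph, expected", [
        (7.4, 7.4, 0.5),                       # equal partition at pH = pKa
        (9.5, 7.4, 10 ** -2.1 / (1 + 10 ** -2.1)),  # ≈ 0.00788
        (-1000.0, 7.4, 1.0),                   # fully unionized base limit
    ])
    def test_values(self, pka, ph, expected):
        assert unionized_fraction(pka, ph) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(2.0, 12.0), st.floats(2.0, 12.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ph(self, pka, ph):
        assert unionized_fraction(pka, ph + 0.1) > unionized_fraction(pka, ph)


class TestTransporterClint:
    def _assay(self, **kw):
        base = dict(papp_ab=1.36, net_efflux_ratio=13.4, filter_surface_area=1.12,
                    cell_count=3.9217, assay_ph=7.4,
                    unionized_fraction=unionized_fraction(9.5, 7.4))
        base.update(kw)
        return TransportAssayRecord(**base)

    def test_zero_at_unit_efflux_ratio(self):
        assert transporter_clint_from_assay(self._assay(net_efflux_ratio=1.0)) == 0.0

    def test_inverse_in_cell_count_linear_in_sa(self):
        base = transporter_clint_from_assay(self._assay())
        assert transporter_clint_from_assay(self._assay(cell_count=2 * 3.9217)) \
            == pytest.approx(base / 2)
        assert transporter_clint_from_assay(self._assay(filter_surface_area=2 * 1.12)) \
            == pytest.approx(2 * base)

    def test_backcalculated_cell_count_reproduces_both_transporters(self):
        """The implied transwell cell count recovers the ABCB1 value it was
        solved for, and independently reproduces the BCRP value."""
        gamma = unionized_fraction(9.5, 7.4)
        cells = implied_assay_cell_count(1.36, 13.4, 1.12, gamma, 73.4)
        assert cells == pytest.approx(3.9217, rel=1e-3)
        bcrp = transporter_clint_from_assay(self._assay(
            papp_ab=0.83, net_efflux_ratio=5.4, cell_count=cells))
        assert bcrp == pytest.approx(15.9, rel=0.005)

    def test_negative_efflux_rejected(self):
        with pytest.raises(ParameterError):
            self._assay(net_efflux_ratio=0.8)


class TestPPSF:
    def test_unity_cases(self):
        assert ppsf(0.011, 0.45, 0.45) == pytest.approx(1.0)
        assert ppsf(1.0, 0.2, 0.45) == pytest.approx(1.0)

    def test_hypoalbuminemia_value_vs_independent_dilution_formula(self):
        """PPSF for the patient albumin matches the standard albumin-dilution
        relation fu2 = 1/(1 + (alb2/alb1)·(1 − fu1)/fu1)."""
        fu1 = 0.011
        scale = ppsf(fu1, 0.31, 0.45)
        assert scale == pytest.approx(1.444, abs=0.001)
        fu2_independent = 1.0 / (1.0 + (0.31 / 0.45) * (1.0 - fu1) / fu1)
        assert fu1 * scale == pytest.approx(fu2_independent, rel=1e-12)
        assert fu1 * scale == pytest.approx(0.0159, abs=2e-4)

    @given(st.floats(0.1, 0.6), st.floats(0.01, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_decreasing_in_albumin(self, albumin, fu):
        lower = ppsf(fu, albumin, 0.45)
        higher = ppsf(fu, albumin * 1.2, 0.45)
        assert higher < lower

    def test_literal_orientation_reverses_direction(self):
        assert ppsf(0.011, 0.31, 0.45, orientation="literal") < 1.0


class TestKdeg:
    @pytest.mark.parametrize("halflife, expected, tol", [
        (27.5, 0.025, 5e-4),          # printed turnover value, 2 s.f.
        (math.log(2.0), 1.0, 1e-12),
        (1.0, 0.6931, 1e-4),
    ])
    def test_values(self, halflife, expected, tol):
        assert kdeg_from_halflife(halflife) == pytest.approx(expected, abs=tol)


class TestFixtureLoading:
    def test_roundtrip_is_lossless(self):
        a, b = load_params(), load_params()
        assert a.compound == b.compound
        assert a.metabolism.cyp_clint == b.metabolism.cyp_clint
        assert a.eo.kon == b.eo.kon

    def test_key_values_load_into_typed_fields(self, params):
        assert params.compound.molecular_weight == 499.6
        assert params.compound.fu_plasma == 0.011
        assert params.distribution.kp_scale == 1.5
        assert params.distribution.k_brt_plasma == 2.89
        assert params.metabolism.cyp_clint["CYP3A4"] == 0.73
        assert params.brain_transport.abcb1_clint == 73.4
        assert params.eo.kon["c797s"] == 0.0026
        assert params.eo.kdeg == pytest.approx(math.log(2) / 27.5)
        assert params.interactions.emax_cyp3a4 == 10.8
        assert params.physiology.hematocrit == 0.33

    def test_fixture_checksums_unchanged(self):
        from pbpkeo.io import verify_fixtures
        assert verify_fixtures()
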