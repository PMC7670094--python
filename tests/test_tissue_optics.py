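"""Unit and property tests for the chromophore and scattering models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxidrs.tissue_optics import (
    CONSTANTS,
    TissueParams,
    ValidationError,
    blood_mu_a,
    dermis_mu_a,
    epidermis_mu_a,
    hb_concentration,
    layer_blood_fractions,
    layer_saturations,
    layer_vessel_diameters,
    melanin_mu_a,
    reduced_scattering,
    vessel_packing_factor,
)


class TestMelanin:
    @pytest.mark.parametrize("lam, beta, expected", [
        (550.0, 0.7, 48.42),      # reference wavelength: power term is unity
        (550.0, 3.3, 48.42),
        (1100.0, 1.0, 24.21),
        (275.0, 2.0, 193.68),
    ])
    def test_values(self, lam, beta, expected):
        assert melanin_mu_a(lam, beta) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_wavelength(self):
        with pytest.raises(ValueError):
            melanin_mu_a(0.0, 2.0)
        with pytest.raises(ValueError):
            melanin_mu_a(-500.0, 2.0)

    @given(beta=st.floats(0.5, 6.0))
    def test_strictly_decreasing_for_positive_slope(self, beta):
        lams = np.linspace(400, 900, 50)
        mu = melanin_mu_a(lams, beta)
        assert np.all(np.diff(mu) < 0)


class TestEpidermis:
    def test_zero_fractions_give_zero(self, chromo, typical_params):
        p = TissueParams(**{**typical_params.__dict__,
                            "f_mel": 0.0, "f_bcaro": 0.0, "f_lyco": 0.0})
        assert epidermis_mu_a(600.0, p, chromo) == 0.0

    def test_pure_melanin_at_reference(self, chromo, typical_params):
        p = TissueParams(**{**typical_params.__dict__, "f_mel": 0.01,
                            "f_bcaro": 0.0, "f_lyco": 0.0})
        assert epidermis_mu_a(550.0, p, chromo) == pytest.approx(0.4842)

    def test_carotenoids_negligible_above_550(self, chromo, typical_params):
        p = TissueParams(**{**typical_params.__dict__, "f_mel": 0.01,
                            "f_bcaro": 0.01, "f_lyco": 0.01})
        mel_only = p.f_mel * melanin_mu_a(700.0, p.beta_mel)
        assert epidermis_mu_a(700.0, p, chromo) == pytest.approx(mel_only,
                                                                 rel=0.01)

    def test_outside_table_range_raises(self, chromo, typical_params):
        with pytest.raises(ValueError):
            epidermis_mu_a(2000.0, typical_params, chromo)

    @given(scale=st.floats(0.1, 5.0))
    def test_homogeneous_in_fractions(self, chromo, typical_params, scale):
        base = dict(typical_params.__dict__)
        p1 = TissueParams(**base)
        base2 = {**base, "f_mel": base["f_mel"] * scale,
                 "f_bcaro": base["f_bcaro"] * scale,
                 "f_lyco": base["f_lyco"] * scale}
        p2 = TissueParams(**base2)
        a1 = epidermis_mu_a(500.0, p1, chromo)
        a2 = epidermis_mu_a(500.0, p2, chromo)
        assert a2 == pytest.approx(scale * a1, rel=1e-9)


class TestLayerDerivations:
    def test_saturations(self):
        assert layer_saturations(0.5, 0.2) == pytest.approx((0.6, 0.4))
        assert layer_saturations(0.5, 0.0) == pytest.approx((0.5, 0.5))

    def test_saturation_range_violation(self):
        with pytest.raises(ValidationError):
            layer_saturations(0.97, 0.1)

    def test_blood_fractions(self):
        assert layer_blood_fractions(0.01, 0.5) == pytest.approx((0.015, 0.005))
        assert layer_blood_fractions(0.01, 0.0) == pytest.approx((0.01, 0.01))
        assert layer_blood_fractions(0.02, -1.0) == pytest.approx((0.0, 0.04))

    def test_blood_fraction_negative_raises(self):
        with pytest.raises(ValidationError):
            layer_blood_fractions(0.01, 1.5)

    def test_vessel_diameters(self):
        assert layer_vessel_diameters(0.02, 0.0) == pytest.approx((0.02, 0.02))
        assert layer_vessel_diameters(0.02, 0.5) == pytest.approx((0.01, 0.03))
        assert layer_vessel_diameters(0.02, 1.0) == pytest.approx((0.0, 0.04))

    @given(s=st.floats(0.0, 1.0), d=st.floats(-1.0, 1.0))
    def test_saturation_mean_preserved(self, s, d):
        try:
            s1, s2 = layer_saturations(s, d)
        except ValidationError:
            return
        assert (s1 + s2) / 2 == pytest.approx(s, abs=1e-12)


class TestBloodAbsorption:
    def test_pure_endpoints(self, chromo):
        lam = 560.0
        assert blood_mu_a(lam, 1.0, 0.0, chromo) == pytest.approx(
            float(chromo.sat(lam)))
        assert blood_mu_a(lam, 0.0, 0.0, chromo) == pytest.approx(
            float(chromo.red(lam)))
        # full met-hemoglobin: independent of saturation
        assert blood_mu_a(lam, 0.3, 1.0, chromo) == pytest.approx(
            float(chromo.met(lam)))
        assert blood_mu_a(lam, 0.9, 1.0, chromo) == pytest.approx(
            float(chromo.met(lam)))

    def test_range_validation(self, chromo):
        with pytest.raises(ValidationError):
            blood_mu_a(600.0, 1.2, 0.0, chromo)
        with pytest.raises(ValidationError):
            blood_mu_a(600.0, 0.5, -0.1, chromo)

    @given(s=st.floats(0.0, 1.0), fm=st.floats(0.0, 1.0),
           lam=st.floats(476.0, 849.0))
    @settings(max_examples=50)
    def test_convex_combination_bounds(self, chromo, s, fm, lam):
        mu = blood_mu_a(lam, s, fm, chromo)
        pure = [float(chromo.sat(lam)), float(chromo.red(lam)),
                float(chromo.met(lam))]
        assert min(pure) - 1e-12 <= mu <= max(pure) + 1e-12


class TestVesselPacking:
    @pytest.mark.parametrize("x, expected", [
        (1.0, 0.63212), (2.0, 0.43233),
    ])
    def test_values(self, x, expected):
        assert vessel_packing_factor(x, 1.0) == pytest.approx(expected,
                                                              abs=1e-5)

    def test_limit_at_zero(self):
        assert vessel_packing_factor(0.0, 0.02) == 1.0
        assert vessel_packing_factor(1e-12, 1.0) == pytest.approx(1.0)

    def test_monotone_decreasing_on_log_grid(self):
        x = np.logspace(-6, 2, 60)
        vals = vessel_packing_factor(x, 1.0)
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals <= 1))

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            vessel_packing_factor(-1.0, 0.02)
        with pytest.raises(ValueError):
            vessel_packing_factor(1.0, -0.02)


class TestDermis:
    def test_zero_blood_gives_zero(self, chromo, typical_params):
        p = TissueParams(**{**typical_params.__dict__, "f_blood": 0.0})
        lam = np.linspace(480, 840, 20)
        assert np.all(dermis_mu_a(lam, p, 1, chromo) == 0.0)
        assert np.all(dermis_mu_a(lam, p, 2, chromo) == 0.0)

    def test_packing_bounds_absorption(self, chromo, typical_params):
        lam = np.linspace(480, 840, 20)
        for layer in (1, 2):
            mu = dermis_mu_a(lam, typical_params, layer, chromo)
            f = layer_blood_fractions(typical_params.f_blood,
                                      typical_params.r_blood)[layer - 1]
            s = layer_saturations(typical_params.s_o2,
                                  typical_params.delta_o2)[layer - 1]
            unpacked = f * blood_mu_a(lam, s, typical_params.f_met, chromo)
            assert np.all(mu <= unpacked + 1e-12)
            assert np.all(mu >= 0)

    def test_small_vessels_approach_homogeneous(self, chromo, typical_params):
        p = TissueParams(**{**typical_params.__dict__, "d_avg": 1e-7})
        f1, _ = layer_blood_fractions(p.f_blood, p.r_blood)
        s1, _ = layer_saturations(p.s_o2, p.delta_o2)
        expected = f1 * blood_mu_a(560.0, s1, p.f_met, chromo)
        assert dermis_mu_a(560.0, p, 1, chromo) == pytest.approx(expected,
                                                                 rel=1e-4)

    def test_invalid_layer(self, chromo, typical_params):
        with pytest.raises(ValueError):
            dermis_mu_a(600.0, typical_params, 3, chromo)


class TestReducedScattering:
    @given(alpha=st.floats(0.2, 10.0), beta=st.floats(0.0, 4.0),
           gamma=st.floats(0.0, 1.0))
    def test_equals_alpha_at_reference(self, alpha, beta, gamma):
        assert reduced_scattering(600.0, alpha, beta, gamma) == \
            pytest.approx(alpha, rel=1e-14)

    def test_mixed_value(self):
        assert reduced_scattering(1200.0, 3.0, 1.0, 0.1) == \
            pytest.approx(1.36875, rel=1e-12)

    def test_pure_mie_power_law(self):
        lam = np.array([500.0, 700.0])
        out = reduced_scattering(lam, 2.0, 1.3, 0.0)
        assert np.allclose(out, 2.0 * (lam / 600.0) ** (-1.3))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            reduced_scattering(600.0, -1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            reduced_scattering(600.0, 1.0, 1.0, 1.5)


class TestHbConcentration:
    def test_conversion_factor(self):
        # 345/64500 * 1e4 = 53.488...; prints as 53.5
        assert 53.45 <= hb_concentration(1.0) <= 53.55
        assert hb_concentration(1.0) == pytest.approx(
            1e4 * CONSTANTS.c_hb_rbc / CONSTANTS.m_hb, rel=1e-14)

    def test_linearity(self):
        assert hb_concentration(0.0) == 0.0
        assert hb_concentration(0.5) == pytest.approx(26.744, abs=0.01)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            hb_concentration(-0.1)


class TestTissueParams:
    def test_invariant_violations_raise(self, typical_params):
        base = dict(typical_params.__dict__)
        for bad in ({"t_epi": 0.0}, {"f_blood": -0.01}, {"alpha": 0.0},
                    {"gamma": 1.2}, {"s_o2": 0.99, "delta_o2": 0.5},
                    {"r_blood": 1.5}, {"r_d": 1.5}):
            with pytest.raises(ValidationError):
                TissueParams(**{**base, **bad})

    def test_array_round_trip(self, typical_params):
        arr = typical_params.as_array()
        again = TissueParams.from_array(arr)
        assert np.allclose(again.as_array(), arr)
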