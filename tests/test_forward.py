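"""Tests for spectrum synthesis and sampling-volume-weighted targets."""

import numpy as np
import pytest

from oxidrs.forward import (
    SpectrumPair,
    default_wavelength_grid,
    forward_record,
    model_spectrum,
    sampling_weights,
    target_values,
    white_reference,
)
from oxidrs.tissue_optics import TissueParams


def _with(params, **kw):
    return TissueParams(**{**params.__dict__, **kw})


class TestWavelengthGrid:
    def test_default_grid(self):
        g = default_wavelength_grid()
        assert g.size == 28
        assert g[0] == 475.0 and g[-1] == 750.0
        assert np.allclose(np.diff(g), np.diff(g)[0])


class TestModelSpectrum:
    def test_no_chromophores_flat_scattering_gives_flat_spectrum(
            self, small_table, chromo, typical_params, grid):
        """With zero absorption and wavelength-independent scattering the
        white-calibrated spectrum is constant over wavelength."""
        p = _with(typical_params, f_mel=0.0, f_bcaro=0.0, f_lyco=0.0,
                  f_blood=0.0, beta=0.0, gamma=0.0)
        spec = model_spectrum(p, small_table, grid, chromo)
        assert np.allclose(spec.i_short, spec.i_short[0], rtol=1e-12)
        assert np.allclose(spec.i_long, spec.i_long[0], rtol=1e-12)
        assert np.all(spec.i_short > 0)

    def test_melanin_darkens_spectrum_more_at_short_wavelengths(
            self, small_table, chromo, typical_params, grid):
        lo = model_spectrum(_with(typical_params, f_mel=0.01),
                            small_table, grid, chromo)
        hi = model_spectrum(_with(typical_params, f_mel=0.1),
                            small_table, grid, chromo)
        assert np.all(hi.i_short < lo.i_short)
        assert np.all(hi.i_long < lo.i_long)
        atten = hi.i_short / lo.i_short
        assert atten[0] < atten[-1]  # stronger attenuation at 475 than 750

    def test_hemoglobin_band_structure(self, small_table, chromo,
                                       typical_params, grid):
        """Blood imprints the 520-590 nm hemoglobin bands on the spectrum."""
        with_blood = model_spectrum(_with(typical_params, f_blood=0.02),
                                    small_table, grid, chromo)
        without = model_spectrum(_with(typical_params, f_blood=0.0),
                                 small_table, grid, chromo)
        band = (grid >= 520) & (grid <= 590)
        ref = (grid >= 650)
        ratio = with_blood.i_long / without.i_long
        band_depth = 1 - ratio[band].mean()
        ref_depth = 1 - ratio[ref].mean()
        assert band_depth > ref_depth + 0.05

    def test_more_blood_darkens_hemoglobin_band(self, small_table, chromo,
                                                typical_params, grid):
        base = model_spectrum(typical_params, small_table, grid, chromo)
        double = model_spectrum(
            _with(typical_params, f_blood=2 * typical_params.f_blood),
            small_table, grid, chromo)
        band = (grid >= 520) & (grid <= 590)
        assert np.all(double.i_short[band] < base.i_short[band])
        assert np.all(double.i_long[band] < base.i_long[band])

    def test_long_channel_dimmer_on_common_scale(self, small_table, chromo,
                                                 dists, grid):
        """On the raw detected-fraction scale the 1.2 mm channel is dimmer
        than the 0.4 mm channel at every wavelength."""
        from oxidrs.dataset import sample_parameters
        from oxidrs.forward import _mua_triplets
        for p in sample_parameters(5, dists, seed=31):
            mua, musp = _mua_triplets(p, grid, chromo)
            raw, _ = small_table.spectrum_sums(p.t_epi, musp, mua)
            assert np.all(raw[1] <= raw[0])

    def test_out_of_grid_scattering_refused(self, small_table, chromo,
                                            typical_params, grid):
        p = _with(typical_params, alpha=50.0)
        with pytest.raises(Exception, match="outside grid"):
            model_spectrum(p, small_table, grid, chromo)


class TestSamplingWeights:
    def test_weights_sum_to_one(self, small_table, chromo, typical_params,
                                grid):
        w = sampling_weights(typical_params, small_table, grid, chromo)
        assert w.shape == (3,)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_absorbing_epidermis_reduces_epidermal_weight(
            self, small_table, chromo, typical_params, grid):
        """Photons with long epidermal paths are preferentially absorbed, so
        strong melanin absorption shrinks the epidermis path share."""
        dark = sampling_weights(_with(typical_params, f_mel=0.3),
                                small_table, grid, chromo)
        fair = sampling_weights(_with(typical_params, f_mel=0.0),
                                small_table, grid, chromo)
        assert dark[0] < fair[0]

    def test_geometric_switch_ignores_absorption(self, small_table, chromo,
                                                 typical_params, grid):
        a = sampling_weights(_with(typical_params, f_mel=0.3), small_table,
                             grid, chromo, absorption_weighted=False)
        b = sampling_weights(_with(typical_params, f_mel=0.0), small_table,
                             grid, chromo, absorption_weighted=False)
        assert np.allclose(a, b, atol=1e-12)


class TestTargets:
    def test_homogeneous_dermis_recovers_inputs(self, typical_params):
        p = _with(typical_params, r_blood=0.0, delta_o2=0.0)
        w = np.array([0.2, 0.3, 0.5])
        tgt = target_values(p, w)
        assert tgt.s_o2 == pytest.approx(p.s_o2, abs=1e-12)
        assert tgt.f_rbc == pytest.approx(0.43 * p.f_blood * 0.8, rel=1e-12)

    def test_no_blood_flags_saturation_undefined(self, typical_params):
        p = _with(typical_params, f_blood=0.0)
        tgt = target_values(p, np.array([0.2, 0.3, 0.5]))
        assert tgt.f_rbc == 0.0
        assert not tgt.saturation_defined

    def test_shallow_sampling_approaches_upper_dermis(self, typical_params):
        from oxidrs.tissue_optics import layer_blood_fractions, layer_saturations
        tgt = target_values(typical_params, np.array([0.3, 0.7, 0.0]))
        f1, _ = layer_blood_fractions(typical_params.f_blood,
                                      typical_params.r_blood)
        s1, _ = layer_saturations(typical_params.s_o2,
                                  typical_params.delta_o2)
        assert tgt.s_o2 == pytest.approx(s1, abs=1e-12)
        assert tgt.f_rbc == pytest.approx(0.43 * 0.7 * f1, rel=1e-12)

    def test_invalid_weights_rejected(self, typical_params):
        with pytest.raises(ValueError):
            target_values(typical_params, np.array([0.5, -0.1, 0.6]))
        with pytest.raises(ValueError):
            target_values(typical_params, np.zeros(3))


class TestForwardRecord:
    def test_combined_pass_matches_separate_calls(self, small_table, chromo,
                                                  typical_params, grid):
        spec, tgt = forward_record(typical_params, small_table, grid, chromo)
        spec2 = model_spectrum(typical_params, small_table, grid, chromo)
        w = sampling_weights(typical_params, small_table, grid, chromo)
        assert np.allclose(spec.i_short, spec2.i_short)
        assert np.allclose(spec.i_long, spec2.i_long)
        assert np.allclose(tgt.weights, w, atol=1e-12)

    def test_white_reference_positive(self, small_table):
        ref = white_reference(small_table)
        assert ref.shape == (2,)
        assert np.all(ref > 0)
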