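"""Despiking, baseline correction, and vector normalization."""

import numpy as np
import pytest

from ramanstack.errors import ConfigError, DataError
from ramanstack.phantom import PhantomConfig, generate_stack
from ramanstack.preprocess import (
    DIALECT_NORMALIZATION_REGION,
    PreprocessConfig,
    baseline_correct,
    baseline_correct_batch,
    despike,
    despike_batch,
    preprocess_stack,
    vector_normalize,
    vector_normalize_batch,
)
from ramanstack.stack import Spectrum

from conftest import gaussian_spectrum


class TestDespike:
    def test_single_spike_on_smooth_band_found_exactly(self, axis918):
        """One cosmic ray on a smooth band: exactly that channel is reported
        and the corrected value is close to the spike-free spectrum."""
        clean = gaussian_spectrum(axis918, 2940.0, 20.0, amplitude=100.0, offset=5.0)
        spiked = clean.intensity.copy()
        spiked[400] += 1000.0
        corrected, idx = despike(Spectrum(axis918, spiked), threshold=8.0, window=7)
        assert idx == [400]
        assert abs(corrected.intensity[400] - clean.intensity[400]) < 2.0
        others = np.ones(len(axis918), dtype=bool)
        others[400] = False
        assert np.array_equal(corrected.intensity[others], spiked[others])

    def test_spike_free_spectrum_untouched(self, axis918):
        s = gaussian_spectrum(axis918, 2940.0, 20.0, amplitude=100.0)
        corrected, idx = despike(s, threshold=8.0)
        assert idx == []
        assert np.array_equal(corrected.intensity, s.intensity)

    def test_flat_zero_spectrum_with_spike_reset_to_zero(self, axis918):
        y = np.zeros(len(axis918))
        y[100] = 500.0
        corrected, idx = despike(Spectrum(axis918, y))
        assert idx == [100]
        assert corrected.intensity[100] == 0.0

    def test_all_constant_spectrum_no_division_error(self, axis918):
        s = Spectrum(axis918, np.full(len(axis918), 3.0))
        corrected, idx = despike(s)
        assert idx == []
        assert np.array_equal(corrected.intensity, s.intensity)

    def test_sharp_real_bands_survive_in_noiseless_limit(self, axis918):
        """The resolution-limited phenylalanine band is not a spike."""
        s = gaussian_spectrum(axis918, 1007.0, 4.5, amplitude=0.7, offset=0.0)
        s = Spectrum(axis918, s.intensity + 2.0 * np.exp(-0.5 * ((axis918 - 2940.0) / 21.0) ** 2))
        corrected, idx = despike(s)
        assert idx == []

    def test_window_must_be_smaller_than_spectrum(self):
        with pytest.raises(ConfigError, match="window"):
            despike_batch(np.zeros((1, 5)), window=7)


class TestBaselineCorrect:
    @pytest.mark.parametrize("method", ["poly2", "autopoly2"])
    def test_exact_quadratic_annihilated(self, axis918, method):
        u = (axis918 - axis918[0]) / (axis918[-1] - axis918[0])
        y = 2.0 - 1.5 * u + 3.0 * u**2
        out = baseline_correct(Spectrum(axis918, y), method=method)
        assert np.max(np.abs(out.intensity)) < 1e-8 * np.max(np.abs(y))

    def test_poly2_is_linear_projection(self, axis918):
        """Adding any degree ≤ 2 polynomial leaves the poly2 result unchanged."""
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, len(axis918)) + 10 * np.exp(-0.5 * ((axis918 - 1500) / 30) ** 2)
        u = (axis918 - axis918[0]) / (axis918[-1] - axis918[0])
        for c in ((1.0, 0.0, 0.0), (0.3, -2.0, 0.0), (0.5, 1.0, -4.0)):
            p = c[0] + c[1] * u + c[2] * u**2
            a = baseline_correct(Spectrum(axis918, s), method="poly2").intensity
            b = baseline_correct(Spectrum(axis918, s + p), method="poly2").intensity
            assert np.max(np.abs(a - b)) < 1e-8 * np.max(np.abs(s))

    def test_autopoly2_recovers_planted_coefficients(self, axis918):
        """Quadratic + one narrow band (<5% of channels): coefficients back
        within 1% relative."""
        u = (axis918 - axis918[0]) / (axis918[-1] - axis918[0])
        planted = np.array([0.5, -0.3, 0.8])
        base = planted[0] + planted[1] * u + planted[2] * u**2
        band = np.exp(-0.5 * ((axis918 - 1007.0) / 15.0) ** 2)  # ±3σ ≈ 3.3% of channels
        _, coeffs = baseline_correct_batch(base + band, axis918, method="autopoly2")
        assert np.all(np.abs(coeffs[0] - planted) <= 0.01 * np.abs(planted))

    def test_autopoly2_preserves_peak_height(self, axis918):
        """Baseline-free band spectrum: peak height changes by < 2%."""
        s = gaussian_spectrum(axis918, 2940.0, 21.0, amplitude=2.0)
        out = baseline_correct(s, method="autopoly2")
        peak = np.argmax(s.intensity)
        change = abs(out.intensity[peak] - s.intensity[peak]) / s.intensity[peak]
        assert change < 0.02

    def test_too_few_channels_rejected(self):
        with pytest.raises(ConfigError, match="channels"):
            baseline_correct_batch(np.zeros((1, 2)), np.array([1.0, 2.0]))


class TestVectorNormalize:
    def test_in_region_norm_is_one(self, axis918):
        rng = np.random.default_rng(1)
        s = Spectrum(axis918, rng.normal(1.0, 0.2, len(axis918)))
        region = (450.0, 3200.0)
        out = vector_normalize(s, region)
        mask = (axis918 >= region[0]) & (axis918 <= region[1])
        assert abs(np.linalg.norm(out.intensity[mask]) - 1.0) < 1e-12

    def test_scale_invariance(self, axis918):
        rng = np.random.default_rng(2)
        y = rng.normal(1.0, 0.2, len(axis918))
        region = (600.0, 2000.0)
        a = vector_normalize(Spectrum(axis918, y), region).intensity
        b = vector_normalize(Spectrum(axis918, 7.3 * y), region).intensity
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_out_of_region_channels_do_not_affect_scale(self, axis918):
        rng = np.random.default_rng(3)
        y = rng.normal(1.0, 0.2, len(axis918))
        region = (900.0, 1100.0)
        perturbed = y.copy()
        perturbed[axis918 > 2000.0] += 100.0
        _, n1 = vector_normalize_batch(y, axis918, region)
        _, n2 = vector_normalize_batch(perturbed, axis918, region)
        assert n1[0] == n2[0]

    def test_zero_norm_error_names_region(self, axis918):
        y = np.zeros(len(axis918))
        y[axis918 > 2000] = 1.0
        with pytest.raises(DataError, match="900"):
            vector_normalize(Spectrum(axis918, y), (900.0, 1100.0))

    def test_dialect_default_regions_are_the_documented_ones(self):
        assert PreprocessConfig(dialect="fixed").normalization_region == (450.0, 3200.0)
        assert PreprocessConfig(dialect="unfixed").normalization_region == (200.0, 1500.0)
        assert DIALECT_NORMALIZATION_REGION["fixed"] == (450.0, 3200.0)
        assert DIALECT_NORMALIZATION_REGION["unfixed"] == (200.0, 1500.0)


class TestPreprocessStack:
    def test_dialect_selects_method_and_region(self):
        assert PreprocessConfig(dialect="fixed").baseline_method == "poly2"
        assert PreprocessConfig(dialect="unfixed").baseline_method == "autopoly2"

    def test_chain_is_idempotent_on_fixed_dialect_phantom(self, tiny_config):
        stack, _ = generate_stack(tiny_config, "control")
        once = preprocess_stack(stack)
        twice = preprocess_stack(once)
        scale = np.max(np.abs(once.data()))
        assert np.max(np.abs(twice.data() - once.data())) < 1e-6 * scale

    def test_all_zero_stack_reports_pixel_coordinates(self, tiny_stack):
        zero = tiny_stack.with_data(np.zeros_like(tiny_stack.data()))
        with pytest.raises(DataError, match=r"plane 0, pixel \(0, 0\)"):
            preprocess_stack(zero)

    def test_despiked_phantom_matches_pre_spike_ground_truth(self):
        """Corrected channels land within 2 counts of the spike-free data."""
        cfg = PhantomConfig(plane_grid=(8, 8), spike_rate=0.1, seed=5)
        stack, truth = generate_stack(cfg, "control")
        assert len(truth.spikes) > 0
        for k, plane in enumerate(stack.planes):
            corrected, _ = despike_batch(plane.pixels())
            corrected = corrected.reshape(plane.data.shape)
            clean = truth.pre_spike[k]
            for (kk, r, c, ch) in truth.spikes_in_plane(k):
                assert abs(corrected[r, c, ch] - clean[r, c, ch]) < 2.0
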