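"""Z=0 designation, layer assignment, band integration, and ratios."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import norm

from ramanstack.errors import ConfigError, DataError
from ramanstack.phantom import PhantomConfig, generate_stack
from ramanstack.preprocess import preprocess_stack, vector_normalize
from ramanstack.profile import (
    assign_layers,
    average_spectrum,
    designate_z0,
    dialect_windows,
    integrate_band,
    lipid_protein_ratio,
    profile_stack,
)
from ramanstack.stack import PlaneImage, Spectrum, ZStack

from conftest import gaussian_spectrum


def stack_with_plane_totals(totals, n_ch=8):
    """Toy stack whose per-plane totals equal the given values."""
    axis = 100.0 + 10.0 * np.arange(n_ch)
    planes = [
        PlaneImage(axis, np.full((1, 1, n_ch), t / n_ch), z=0.5 * k)
        for k, t in enumerate(totals)
    ]
    return ZStack(planes, 0.5)


class TestDesignateZ0:
    def test_argmax_of_plane_totals(self):
        assert designate_z0(stack_with_plane_totals([10.0, 50.0, 30.0])) == 1

    def test_tie_broken_toward_lowest_z(self):
        assert designate_z0(stack_with_plane_totals([50.0, 50.0, 10.0])) == 0

    def test_phantom_z0_falls_in_the_media(self, tiny_config):
        """The attenuation focus sits in the media, so the brightest plane
        is a media plane and the upper planes are dimmer."""
        stack, truth = generate_stack(tiny_config, "control")
        z0 = designate_z0(stack)
        assert truth.labels[z0] == "media"
        totals = stack.plane_totals()
        assert totals[-1] < totals[z0]  # topmost endothelium plane is dimmer


class TestAssignLayers:
    def test_three_planes_one_upper(self):
        a = assign_layers(stack_with_plane_totals([50.0, 40.0, 30.0]), n_upper=1)
        assert a.labels == ["lower", "lower", "upper"]
        assert a.z0_index == 0

    def test_zero_threshold_excludes_nothing(self):
        a = assign_layers(stack_with_plane_totals([50.0, 1e-6, 30.0]),
                          signal_fraction_threshold=0.0)
        assert "excluded" not in a.labels

    def test_dim_top_plane_excluded_next_becomes_upper(self):
        totals = [100.0, 80.0, 60.0, 40.0, 1.0]  # top plane at 1% of Z=0
        a = assign_layers(stack_with_plane_totals(totals), n_upper=1,
                          signal_fraction_threshold=0.1)
        assert a.labels == ["lower", "lower", "lower", "upper", "excluded"]

    def test_n_upper_must_leave_a_lower_plane(self):
        with pytest.raises(ConfigError, match="n_upper"):
            assign_layers(stack_with_plane_totals([10.0, 20.0]), n_upper=2)


class TestAverageSpectrum:
    def test_identical_pixels_average_to_any_pixel(self):
        axis = [1.0, 2.0, 3.0]
        plane = PlaneImage(axis, np.tile([1.0, 2.0, 3.0], (2, 2, 1)), z=0.0)
        assert np.array_equal(average_spectrum(plane).intensity, [1.0, 2.0, 3.0])

    def test_two_pixel_mean(self):
        axis = [1.0, 2.0]
        data = np.array([[[0.0, 0.0], [2.0, 4.0]]])
        assert np.array_equal(average_spectrum(PlaneImage(axis, data, z=0.0)).intensity,
                              [1.0, 2.0])

    def test_averaging_reduces_noise_as_sqrt_n(self):
        """Per-channel sd of the average ≈ σ/√N over phantom replicates."""
        n_px, sigma = 16, 0.05
        cfg = PhantomConfig(plane_grid=(4, 4), noise_sd=sigma, spike_rate=0.0,
                            baseline_coeffs_range=((0.0, 0.0),) * 3)
        devs = []
        for seed in range(200):
            stack, truth = generate_stack(replace(cfg, seed=seed), "control")
            avg = average_spectrum(stack.planes[0]).intensity
            devs.append(avg - truth.noiseless[0])
        sd = np.std(np.asarray(devs), axis=0).mean()
        assert abs(sd - sigma / np.sqrt(n_px)) < 0.2 * sigma / np.sqrt(n_px)


class TestIntegrateBand:
    def test_zero_spectrum_integrates_to_zero(self, axis918):
        assert integrate_band(Spectrum(axis918, np.zeros(918)), (993.0, 1023.0)) == 0.0

    def test_gaussian_matches_closed_form_within_half_percent(self):
        """Trapezoid vs the normal-CDF closed form for a σ=4 Gaussian."""
        axis = np.arange(900.0, 1130.0, 1.0)
        a_amp, sigma, center = 1.0, 4.0, 1007.0
        s = gaussian_spectrum(axis, center, sigma, amplitude=a_amp)
        got = integrate_band(s, (993.0, 1023.0))
        expected = a_amp * sigma * np.sqrt(2 * np.pi) * (
            norm.cdf((1023.0 - center) / sigma) - norm.cdf((993.0 - center) / sigma)
        )
        assert abs(got - expected) / expected < 0.005

    def test_linearity_in_intensity(self, axis918):
        rng = np.random.default_rng(4)
        y = rng.uniform(0, 1, 918)
        w = (2825.0, 3030.0)
        assert integrate_band(Spectrum(axis918, 2 * y), w) == pytest.approx(
            2 * integrate_band(Spectrum(axis918, y), w), rel=1e-12
        )

    def test_window_outside_axis_error_names_span(self, axis918):
        with pytest.raises(ConfigError, match="3200"):
            integrate_band(Spectrum(axis918, np.zeros(918)), (3500.0, 3600.0))


class TestLipidProteinRatio:
    def test_identical_gaussians_in_both_windows_give_ratio_one(self):
        # 1 cm⁻¹ grid so both centers share the same sampling phase
        axis = np.arange(900.0, 3101.0, 1.0)
        y = (np.exp(-0.5 * ((axis - 2940.0) / 5.0) ** 2)
             + np.exp(-0.5 * ((axis - 1007.0) / 5.0) ** 2))
        # symmetric 30 cm⁻¹ windows around both centers
        s = Spectrum(axis, y)
        r = integrate_band(s, (2925.0, 2955.0)) / integrate_band(s, (992.0, 1022.0))
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_dialect_windows_are_verbatim(self):
        f = dialect_windows("fixed")
        u = dialect_windows("unfixed")
        assert f["lipid_CH"].window == (2825.0, 3030.0)
        assert f["protein_phe"].window == (993.0, 1023.0)
        assert u["lipid_CH"].window == (2820.0, 3012.0)
        assert u["protein_phe"].window == (997.0, 1016.0)

    def test_scale_invariance_of_ratio(self, axis918):
        rng = np.random.default_rng(5)
        y = rng.uniform(0.1, 1.0, 918)
        r1 = lipid_protein_ratio(Spectrum(axis918, y))["ratio"]
        r2 = lipid_protein_ratio(Spectrum(axis918, 13.7 * y))["ratio"]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_nonpositive_protein_integral_rejected(self, axis918):
        y = np.exp(-0.5 * ((axis918 - 2940.0) / 20.0) ** 2)  # no phe band at all
        with pytest.raises(DataError, match="undefined"):
            lipid_protein_ratio(Spectrum(axis918, y - 0.001))

    def test_control_endothelium_ratio_exceeds_media(self, noiseless_config):
        """Control phantom: upper-plane lipid/protein ratio > every lower plane."""
        stack, _ = generate_stack(noiseless_config, "control")
        res = profile_stack(preprocess_stack(stack))
        upper = res.planes[res.planes["label"] == "upper"]["ratio"]
        lower = res.planes[res.planes["label"] == "lower"]["ratio"]
        assert upper.min() > lower.max()


class TestProfileStack:
    def test_hand_built_compartment_means(self, axis918):
        """Three single-pixel planes with hand-computed integrals."""
        base = np.exp(-0.5 * ((axis918 - 2940.0) / 20.0) ** 2) \
            + np.exp(-0.5 * ((axis918 - 1007.0) / 4.5) ** 2)
        scales = [1.0, 0.9, 0.8]  # plane 0 brightest → z0
        planes = [
            PlaneImage(axis918, (s * base).reshape(1, 1, -1), z=0.5 * k)
            for k, s in enumerate(scales)
        ]
        res = profile_stack(ZStack(planes, 0.5), dialect="fixed", n_upper=1)
        expected = [lipid_protein_ratio(Spectrum(axis918, s * base)) for s in scales]
        comp = res.compartments.set_index("compartment")
        assert comp.loc["upper", "I_lipid"] == pytest.approx(expected[2]["I_lipid"], rel=1e-12)
        assert comp.loc["lower", "I_lipid"] == pytest.approx(
            (expected[0]["I_lipid"] + expected[1]["I_lipid"]) / 2, rel=1e-12
        )
        assert comp.loc["all", "ratio"] == pytest.approx(
            np.mean([e["ratio"] for e in expected]), rel=1e-12
        )

    def test_all_compartment_independent_of_split(self, tiny_stack):
        pre = preprocess_stack(tiny_stack)
        r1 = profile_stack(pre, n_upper=1).compartments.set_index("compartment")
        r2 = profile_stack(pre, n_upper=2).compartments.set_index("compartment")
        for m in ("I_lipid", "I_protein", "ratio"):
            assert r1.loc["all", m] == pytest.approx(r2.loc["all", m], rel=1e-12)

    def test_average_then_integrate_commutes_with_integrate_then_average(self, axis918):
        rng = np.random.default_rng(6)
        data = rng.uniform(0, 1, size=(3, 4, 918))
        plane = PlaneImage(axis918, data, z=0.0)
        w = (2825.0, 3030.0)
        a = integrate_band(average_spectrum(plane), w)
        b = np.mean([integrate_band(Spectrum(axis918, px), w) for px in plane.pixels()])
        assert a == pytest.approx(b, rel=1e-10)

    def test_noiseless_recovery_matches_generator_truth(self, noiseless_config):
        """Pipeline R per plane equals the same statistic evaluated on the
        generator's pure mixture spectrum (rendering, per-pixel baseline
        randomization, averaging, and stack plumbing add nothing)."""
        cfg = replace(noiseless_config, baseline_coeffs_range=((0.1, 0.3), (-0.2, 0.2), (0.0, 0.4)))
        stack, truth = generate_stack(cfg, "control")
        res = profile_stack(preprocess_stack(stack))
        from ramanstack.preprocess import baseline_correct

        for _, row in res.planes.iterrows():
            k = int(row["plane"])
            oracle_s = Spectrum(stack.axis, truth.noiseless[k].copy())
            oracle_s = baseline_correct(oracle_s, method="poly2")
            oracle_s = vector_normalize(oracle_s, (450.0, 3200.0))
            oracle = lipid_protein_ratio(oracle_s)
            assert row["ratio"] == pytest.approx(oracle["ratio"], rel=1e-6)
            assert row["I_protein"] == pytest.approx(oracle["I_protein"], rel=1e-6)

    def test_metastasis_raises_upper_protein_integral(self, noiseless_config):
        ctrl, _ = generate_stack(noiseless_config, "control")
        met, _ = generate_stack(noiseless_config, "metastasis")
        c = profile_stack(preprocess_stack(ctrl)).compartments.set_index("compartment")
        m = profile_stack(preprocess_stack(met)).compartments.set_index("compartment")
        assert m.loc["upper", "I_protein"] > c.loc["upper", "I_protein"]
        assert m.loc["lower", "I_protein"] == pytest.approx(c.loc["lower", "I_protein"], rel=1e-12)
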