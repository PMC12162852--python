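import numpy as np
import pytest

from irsyn.preprocess import (average_spectra, correct_baseline,
                              correct_water_vapor, difference_spectrum,
                              group_difference, normalize_amide1, smooth)
from irsyn.spectra_io import Spectrum
from irsyn.synthetic_data import (BandShape, ConformerFractions,
                                  mixture_spectrum, vapor_reference)


def band_spectrum(grid, center=1650.0, fwhm=40.0, amplitude=1.0):
    # gaussian: negligible tails at the baseline anchors and vapor window
    return Spectrum(grid.copy(),
                    amplitude * BandShape(center, fwhm, "gaussian").profile(grid))


class TestAverage:
    def test_average_of_identical_spectra_is_identity(self, gaussian_spectrum):
        out = average_spectra([gaussian_spectrum] * 5)
        np.testing.assert_allclose(out.absorbance, gaussian_spectrum.absorbance,
                                   rtol=1e-12)
        assert out.meta["trace"][-1]["n_averaged"] == 5

    def test_average_of_s_and_minus_s_is_zero(self, gaussian_spectrum):
        neg = gaussian_spectrum.with_absorbance(-gaussian_spectrum.absorbance)
        out = average_spectra([gaussian_spectrum, neg])
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-18)

    def test_averaging_reduces_noise_as_sqrt_n(self, grid):
        """100 replicates reduce residual noise sd to ~sigma/10."""
        rng = np.random.default_rng(0)
        sigma = 1e-4
        truth = BandShape(1650.0, 40.0).profile(grid)
        reps = [Spectrum(grid.copy(), truth + rng.normal(0, sigma, grid.size))
                for _ in range(100)]
        resid = average_spectra(reps).absorbance - truth
        assert np.std(resid) == pytest.approx(sigma / 10, rel=0.2)

    def test_grid_mismatch_rejected(self, grid, gaussian_spectrum):
        other = Spectrum(grid[:-1].copy(), np.zeros(grid.size - 1))
        with pytest.raises(ValueError, match="grid mismatch"):
            average_spectra([gaussian_spectrum, other])


class TestDifference:
    def test_self_difference_is_zero(self, gaussian_spectrum):
        out = difference_spectrum(gaussian_spectrum, gaussian_spectrum)
        np.testing.assert_array_equal(out.absorbance, 0.0)

    def test_background_cancels_exactly(self, grid):
        band = band_spectrum(grid)
        bg = Spectrum(grid.copy(), 0.5 + 1e-4 * grid)
        sample = bg.with_absorbance(bg.absorbance + band.absorbance)
        out = difference_spectrum(sample, bg)
        np.testing.assert_allclose(out.absorbance, band.absorbance, atol=1e-15)


class TestWaterVapor:
    @pytest.mark.parametrize("alpha", [-1.0, 0.0, 0.01, 0.3, 2.0])
    def test_alpha_recovered_exactly_noiseless(self, grid, alpha):
        vref = vapor_reference(grid)
        clean = band_spectrum(grid, fwhm=20.0)  # no structure in 1700-1900
        contaminated = clean.with_absorbance(
            clean.absorbance + alpha * vref.absorbance)
        out = correct_water_vapor(contaminated, vref)
        fitted = out.meta["trace"][-1]["alpha"]
        assert fitted == pytest.approx(alpha, abs=1e-6)
        np.testing.assert_allclose(out.absorbance, clean.absorbance, atol=1e-9)

    def test_vapor_free_spectrum_gives_zero_alpha(self, grid):
        out = correct_water_vapor(band_spectrum(grid, fwhm=20.0),
                                  vapor_reference(grid))
        assert abs(out.meta["trace"][-1]["alpha"]) <= 1e-8

    def test_pure_vapor_corrected_to_zero_in_window(self, grid):
        vref = vapor_reference(grid)
        out = correct_water_vapor(vref, vref)
        _, vals = out.window(1700, 1900)
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_degenerate_reference_rejected(self, grid, gaussian_spectrum):
        flat = Spectrum(grid.copy(), np.full(grid.size, 0.5))
        with pytest.raises(ValueError, match="degenerate"):
            correct_water_vapor(gaussian_spectrum, flat)


class TestBaseline:
    def test_linear_ramp_removed_exactly(self, grid):
        ramp = Spectrum(grid.copy(), 3e-4 * grid - 0.1)
        out = correct_baseline(ramp)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-10)

    def test_band_on_ramp_recovered(self, grid):
        band = band_spectrum(grid, fwhm=30.0)  # negligible at anchors
        ramp = 2e-4 * grid + 0.05
        out = correct_baseline(band.with_absorbance(band.absorbance + ramp))
        np.testing.assert_allclose(out.absorbance, band.absorbance, atol=1e-8)

    def test_idempotent_on_flat_spectrum(self, grid):
        flat = Spectrum(grid.copy(), np.zeros(grid.size))
        out = correct_baseline(flat)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_empty_anchor_window_rejected(self, grid, gaussian_spectrum):
        with pytest.raises(ValueError, match="anchor"):
            correct_baseline(gaussian_spectrum, anchors=((2000, 2100), (1480, 1490)))

    def test_rubber_band_removes_curved_baseline(self, grid):
        band = band_spectrum(grid, fwhm=30.0, amplitude=1e-3)
        curved = 1e-8 * (grid - 1700.0) ** 2 + 2e-4
        s = band.with_absorbance(band.absorbance + curved)
        out = correct_baseline(s, method="rubber_band")
        # baseline gone, band height preserved, result non-negative
        assert out.absorbance.min() >= -1e-12
        _, vals = out.window(1600, 1700)
        assert vals.max() == pytest.approx(1e-3, rel=0.05)

    def test_unknown_baseline_method_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError, match="unknown baseline"):
            correct_baseline(gaussian_spectrum, method="spline")


class TestSmooth:
    def test_polynomial_reproduced_in_interior(self, grid):
        x = (grid - grid.mean()) / 100.0
        poly = Spectrum(grid.copy(), 0.3 + 0.2 * x + 0.1 * x**2 + 0.05 * x**3)
        out = smooth(poly, 9, 3)
        np.testing.assert_allclose(out.absorbance[4:-4], poly.absorbance[4:-4],
                                   atol=1e-9)

    def test_white_noise_variance_reduced(self, grid):
        rng = np.random.default_rng(1)
        s = Spectrum(grid.copy(), rng.normal(0, 1e-4, grid.size))
        out = smooth(s, 9, 3)
        assert out.absorbance.var() < s.absorbance.var()
        assert out.meta["smoothed"] is True

    def test_impulse_response_has_window_width(self, grid):
        a = np.zeros(grid.size)
        a[grid.size // 2] = 1.0
        out = smooth(Spectrum(grid.copy(), a), 9, 3)
        nz = np.nonzero(np.abs(out.absorbance) > 1e-12)[0]
        assert nz.size == 9
        # symmetric kernel
        np.testing.assert_allclose(out.absorbance[nz],
                                   out.absorbance[nz][::-1], atol=1e-12)

    def test_invalid_window_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError):
            smooth(gaussian_spectrum, 8, 3)
        with pytest.raises(ValueError):
            smooth(gaussian_spectrum, 3, 3)


class TestNormalize:
    def test_amide1_max_becomes_one(self, grid):
        s = band_spectrum(grid, amplitude=2.0)
        out = normalize_amide1(s)
        _, vals = out.window(1600, 1700)
        assert vals.max() == pytest.approx(1.0)
        np.testing.assert_allclose(out.absorbance * 2.0, s.absorbance, atol=1e-12)

    def test_idempotent(self, grid):
        out1 = normalize_amide1(band_spectrum(grid, amplitude=3.0))
        out2 = normalize_amide1(out1)
        np.testing.assert_allclose(out1.absorbance, out2.absorbance, atol=1e-15)

    def test_gain_invariance(self, grid):
        s = band_spectrum(grid, amplitude=1.3)
        g = s.with_absorbance(s.absorbance * 7.7)
        np.testing.assert_allclose(normalize_amide1(s).absorbance,
                                   normalize_amide1(g).absorbance, atol=1e-12)

    def test_nonpositive_max_rejected(self, grid):
        s = Spectrum(grid.copy(), -np.ones(grid.size))
        with pytest.raises(ValueError, match="nonpositive"):
            normalize_amide1(s)


class TestGroupDifference:
    def test_identical_groups_give_zero(self, grid):
        s = band_spectrum(grid)
        out = group_difference([s, s], [s])
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_swapped_arguments_negate(self, grid):
        pos = [Spectrum(grid.copy(), 1e-3 * mixture_spectrum(
            ConformerFractions.from_beta(0.6), grid))]
        ctl = [Spectrum(grid.copy(), 2e-3 * mixture_spectrum(
            ConformerFractions.from_beta(0.2), grid))]
        d1 = group_difference(pos, ctl)
        d2 = group_difference(ctl, pos)
        np.testing.assert_allclose(d1.absorbance, -d2.absorbance, atol=1e-12)

    def test_beta_enriched_positives_show_sign_pattern(self, grid):
        """Positive lobe near 1624, negative lobe near 1650-1656 cm-1."""
        pos = [Spectrum(grid.copy(), mixture_spectrum(
            ConformerFractions.from_beta(b), grid)) for b in (0.5, 0.6)]
        ctl = [Spectrum(grid.copy(), mixture_spectrum(
            ConformerFractions.from_beta(b), grid)) for b in (0.2, 0.3)]
        d = group_difference(pos, ctl)
        nu_pos, a_pos = d.window(1615, 1635)
        nu_neg, a_neg = d.window(1645, 1665)
        assert a_pos.max() > 0
        assert a_neg.min() < 0

    def test_empty_group_rejected(self, gaussian_spectrum):
        with pytest.raises(ValueError):
            group_difference([], [gaussian_spectrum])


def test_canonical_stage_order_is_traced(noiseless_config):
    """The processing chain runs average -> vapor -> baseline -> difference
    -> smooth, and each stage is recorded in the trace."""
    from irsyn.pipeline import process_run
    from irsyn.synthetic_data import simulate_measurement_run

    run = simulate_measurement_run(ConformerFractions.from_beta(0.3), 1e-3,
                                   noiseless_config,
                                   rng=np.random.default_rng(0))
    smoothed, _ = process_run(run, vapor_reference(noiseless_config.grid()))
    stages = [t["stage"] for t in smoothed.meta["trace"]]
    assert stages == ["average", "water_vapor", "baseline", "difference", "smooth"]
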