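import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopysif.forward import default_hires_grid, simulate_downwelling, DEFAULT_BANDS
from canopysif.instrument import (
    DEFAULT_INSTRUMENT,
    DEFAULT_KERNEL,
    IntegrationTimeState,
    NoiseModel,
    SmoothingKernelSpec,
    add_noise,
    adjacent_average,
    build_kernel,
    detector_counts,
    noise_ensemble,
    optimize_integration_time,
    simulate_acquisition,
    smooth_and_resample,
    snr_at,
)
from canopysif.spectra import Spectrum, uniform_grid


class TestKernel:
    def test_default_tabulation_has_91_points(self):
        offsets, weights = build_kernel(DEFAULT_KERNEL)
        assert offsets.size == 91 and weights.size == 91

    def test_kernel_symmetric_and_unimodal(self):
        offsets, weights = build_kernel(DEFAULT_KERNEL)
        assert np.allclose(weights, weights[::-1])
        assert np.all(np.diff(weights[:46]) > 0)

    def test_truncated_mass_matches_gaussian_integral(self):
        # independent oracle: the kernel is a unit-mass Gaussian of FWHM
        # sqrt(0.9^2 - 0.01^2); its mass within +-0.45 nm is erf(sqrt(ln 2))
        # evaluated for that FWHM ~ 0.7609
        _, weights = build_kernel(DEFAULT_KERNEL)
        fwhm = math.sqrt(0.9**2 - 0.01**2)
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        oracle = math.erf(0.45 / (sigma * math.sqrt(2.0)))
        assert abs(weights.sum() * 0.01 - oracle) < 0.01

    def test_degenerate_kernel_rejected(self):
        with pytest.raises(ValueError):
            SmoothingKernelSpec(fwhm_d=0.01, ssi_o=0.01)


class TestSmoothing:
    def test_constant_input_preserved_exactly(self):
        grid = default_hires_grid()
        s = Spectrum(grid, np.full_like(grid, 3.7), "radiance")
        out = smooth_and_resample(s)
        assert np.allclose(out.values, 3.7, rtol=0, atol=1e-12)

    def test_narrow_line_broadened_to_instrument_resolution(self):
        grid = default_hires_grid()
        line = np.where(np.abs(grid - 700.121) < 0.005, 1.0, 0.0)
        _, w = build_kernel(DEFAULT_KERNEL)
        conv = np.convolve(line, w / w.sum(), mode="same")
        half = conv.max() / 2.0
        above = np.nonzero(conv >= half)[0]
        # linear interpolation of the half-maximum crossings
        lo, hi = above[0], above[-1]
        left = grid[lo - 1] + (half - conv[lo - 1]) / (conv[lo] - conv[lo - 1]) * 0.01
        right = grid[hi] + (conv[hi] - half) / (conv[hi] - conv[hi + 1]) * 0.01
        assert abs((right - left) - 0.9) < 0.02

    def test_monotone_input_stays_monotone(self):
        grid = default_hires_grid()
        s = Spectrum(grid, np.linspace(1.0, 2.0, grid.size) ** 2, "radiance")
        out = smooth_and_resample(s)
        assert np.all(np.diff(out.values) > 0)

    def test_insufficient_coverage_is_an_error(self):
        grid = uniform_grid(500.0, 600.0, 0.01)
        with pytest.raises(ValueError, match="cover"):
            smooth_and_resample(Spectrum(grid, np.ones_like(grid), "radiance"))


class TestNoiseModel:
    def test_snr_at_reference_counts(self):
        model = NoiseModel()
        assert snr_at(model.counts_ref, model) == 1000.0
        assert np.isclose(snr_at(model.counts_ref / 4.0, model), 500.0)
        assert abs(snr_at(50000.0, NoiseModel()) - 877.06) < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            snr_at(-1.0, NoiseModel())

    def test_zero_spectrum_passes_through_unchanged(self):
        grid = uniform_grid(500, 510, 0.5)
        s = Spectrum(grid, np.zeros_like(grid), "radiance")
        out = add_noise(s, NoiseModel(seed=1))
        assert np.array_equal(out.values, s.values)

    def test_realizations_reproducible_and_order_independent(self):
        grid = uniform_grid(500, 510, 0.5)
        s = Spectrum(grid, np.linspace(1, 2, grid.size), "radiance")
        model = NoiseModel(seed=42)
        big = noise_ensemble(s, 8, model, stream=1)
        small = noise_ensemble(s, 3, model, stream=1)
        assert np.array_equal(big[:3], small)
        again = add_noise(s, model, stream=1, index=2)
        assert np.array_equal(again.values, big[2])

    def test_ensemble_moments_match_model(self):
        grid = uniform_grid(600, 700, 1.0)
        s = Spectrum(grid, 1.0 + np.sin(grid / 20.0) ** 2, "radiance")
        model = NoiseModel(seed=7)
        ens = noise_ensemble(s, 2000, model)
        vmax = s.values.max()
        snr = model.snr_ref * np.sqrt(s.values / vmax * model.stretch_target / model.counts_ref)
        expected_sd = s.values / snr
        se = expected_sd / np.sqrt(2000)
        assert np.all(np.abs(ens.mean(0) - s.values) < 4 * se)
        i = s.values.argmax()
        assert abs(ens[:, i].std(ddof=1) - expected_sd[i]) / expected_sd[i] < 0.10


class TestIntegrationTime:
    @pytest.mark.parametrize(
        "it_init,counts_init,counts_opt,expected",
        [(0.100, 25000, 50000, 0.200), (0.123, 52000, 52000, 0.123), (0.150, 60000, 52000, 0.130)],
    )
    def test_single_step_formula(self, it_init, counts_init, counts_opt, expected):
        state = IntegrationTimeState(it_init=it_init, counts_init=counts_init, counts_opt=counts_opt)
        assert np.isclose(optimize_integration_time(state), expected)

    def test_zero_counts_signals_unmeasurable_target(self):
        with pytest.raises(ValueError, match="unmeasurable"):
            optimize_integration_time(IntegrationTimeState(it_init=0.1, counts_init=0.0, counts_opt=52000))


class TestDetector:
    @pytest.fixture()
    def radiance(self):
        grid = uniform_grid(500, 860, 2.0)
        return Spectrum(grid, 100.0 + 80.0 * np.sin(grid / 40.0) ** 2, "radiance")

    def test_zero_radiance_gives_dark_counts(self):
        grid = uniform_grid(500, 510, 0.5)
        out = detector_counts(Spectrum(grid, np.zeros_like(grid), "radiance"), 0.1)
        assert np.all(out.values == DEFAULT_INSTRUMENT.dark_counts)

    def test_dark_subtracted_counts_linear_in_time(self, radiance):
        c1 = detector_counts(radiance, 0.02).values - DEFAULT_INSTRUMENT.dark_counts
        c2 = detector_counts(radiance, 0.04).values - DEFAULT_INSTRUMENT.dark_counts
        assert np.allclose(c2, 2 * c1)

    def test_optimization_closure_reaches_target(self, radiance):
        spec = DEFAULT_INSTRUMENT
        probe = detector_counts(radiance, 0.01, spec)
        state = IntegrationTimeState(
            it_init=0.01, counts_init=probe.values.max() - spec.dark_counts, counts_opt=spec.counts_opt
        )
        it_opt = optimize_integration_time(state)
        remeasured = detector_counts(radiance, it_opt, spec)
        assert abs(remeasured.values.max() - spec.dark_counts - spec.counts_opt) < 1.0

    def test_acquisition_sequence_hits_target_fraction(self):
        grid = default_hires_grid()
        E = simulate_downwelling(30.0, DEFAULT_BANDS, grid)
        panel = Spectrum(grid, E.values / np.pi, "radiance")
        target = Spectrum(grid, E.values * 0.4 / np.pi, "radiance")
        report = simulate_acquisition(panel, target)
        for frac in (report.panel_peak_fraction, report.target_peak_fraction):
            assert abs(frac - (0.80 + DEFAULT_INSTRUMENT.dark_counts / DEFAULT_INSTRUMENT.saturation_counts)) < 0.01
        assert report.total_duration > 2 * 3.5
        assert report.target_it > report.panel_it  # darker target, longer exposure


class TestAdjacentAverage:
    @pytest.fixture()
    def toy(self):
        return Spectrum(uniform_grid(500, 504, 1.0), np.array([0.0, 3.0, 0.0, 3.0, 0.0]), "radiance")

    def test_window_one_is_identity(self, toy):
        assert np.array_equal(adjacent_average(toy, 1).values, toy.values)

    def test_hand_computed_shrunken_edges(self, toy):
        assert np.allclose(adjacent_average(toy, 3).values, [1.5, 1.0, 2.0, 1.0, 1.5])

    def test_even_window_rejected(self, toy):
        with pytest.raises(ValueError):
            adjacent_average(toy, 4)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_constant_input_invariant(self, seed):
        rng = np.random.default_rng(seed)
        c = float(rng.uniform(0.1, 10.0))
        n = int(rng.integers(3, 30))
        s = Spectrum(uniform_grid(500, 500 + n - 1, 1.0), np.full(n, c), "radiance")
        assert np.allclose(adjacent_average(s, 3).values, c)
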