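import numpy as np
import pytest

from canopysif.forward import (
    DEFAULT_BANDS,
    O2A_BAND,
    O2B_BAND,
    bare_land_scene,
    compose_upwelling,
    default_hires_grid,
    simulate_downwelling,
)
from canopysif.retrieval import (
    RetrievalWindow,
    bundled_windows,
    candidate_windows,
    fld,
    retrieve,
    retrieve_ensemble,
    selected_window,
    sfm,
    three_fld,
    three_fld_weights,
)
from canopysif.spectra import Spectrum, uniform_grid


def make_pair(grid, sza=0.0, bands=(O2A_BAND,), r=None, f=None):
    E = simulate_downwelling(sza, bands, grid)
    r = np.full_like(grid, 0.5) if r is None else r
    f = np.zeros_like(grid) if f is None else f
    L = Spectrum(grid, E.values * r / np.pi + f, "radiance")
    return E, L


class TestWindowValidation:
    def test_left_shoulder_must_be_shorter(self):
        with pytest.raises(ValueError):
            RetrievalWindow("FLD", "O2A", 760.519, 761.0)

    def test_3fld_requires_right_shoulder(self):
        with pytest.raises(ValueError):
            RetrievalWindow("3FLD", "O2A", 760.519, 755.0)

    def test_sfm_degree_ordering(self):
        with pytest.raises(ValueError):
            RetrievalWindow("SFM", "O2A", 760.519, 755.0, 766.0, degree_r=1, degree_f=2)

    def test_degrees_rejected_for_fld(self):
        with pytest.raises(ValueError):
            RetrievalWindow("FLD", "O2A", 760.519, 755.0, degree_r=1, degree_f=1)


class TestFld:
    def test_exact_for_constant_reflectance_and_fluorescence(self, o2a_grid):
        E, L = make_pair(o2a_grid, f=np.full_like(o2a_grid, 0.8))
        w = RetrievalWindow("FLD", "O2A", 760.519, 757.019)
        assert abs(fld(E, L, w).f_value - 0.8) < 1e-9

    def test_zero_fluorescence_returns_zero(self, o2a_grid):
        E, L = make_pair(o2a_grid)
        w = RetrievalWindow("FLD", "O2A", 760.519, 757.019)
        assert abs(fld(E, L, w).f_value) < 1e-9

    def test_scale_invariant_in_downwelling_units(self, o2a_grid):
        E, L = make_pair(o2a_grid, f=np.full_like(o2a_grid, 0.8))
        w = RetrievalWindow("FLD", "O2A", 760.519, 757.019)
        E_panel = Spectrum(o2a_grid, E.values / np.pi, "radiance")
        assert np.isclose(fld(E, L, w).f_value, fld(E_panel, L, w).f_value)

    def test_no_absorption_contrast_is_degenerate(self, o2a_grid):
        E = Spectrum(o2a_grid, np.full_like(o2a_grid, 1000.0), "irradiance")
        L = Spectrum(o2a_grid, E.values * 0.5 / np.pi, "radiance")
        w = RetrievalWindow("FLD", "O2A", 760.519, 757.019)
        with pytest.raises(ValueError, match="degenerate"):
            fld(E, L, w)

    def test_overestimates_on_vegetated_scene(self, ref_obs):
        res = retrieve(ref_obs.downwelling, ref_obs.upwelling, selected_window("O2A", "FLD"))
        assert res.f_value > ref_obs.truth_o2a


class TestThreeFld:
    def test_exact_for_linear_reflectance(self, o2a_grid):
        # flat continuum + symmetric on-grid shoulders see equal continuum,
        # the regime in which the interpolated-shoulder estimator is exact
        E = Spectrum(o2a_grid, 1000.0 * O2A_BAND.transmittance(o2a_grid), "irradiance")
        r = 0.4 + 0.002 * (o2a_grid - 760.519)
        L = Spectrum(o2a_grid, E.values * r / np.pi + 0.5, "radiance")
        w = RetrievalWindow("3FLD", "O2A", 760.519, 755.519, 765.519)
        assert abs(three_fld(E, L, w).f_value - 0.5) < 1e-9

    def test_weights_sum_to_one_for_all_bundled_windows(self):
        for w in bundled_windows():
            if w.algorithm == "3FLD":
                w_l, w_r = three_fld_weights(w)
                assert np.isclose(w_l + w_r, 1.0)
                assert 0 < w_l < 1

    def test_less_biased_than_fld_on_curved_scene(self, ref_obs):
        f3 = retrieve(ref_obs.downwelling, ref_obs.upwelling, selected_window("O2A", "3FLD")).f_value
        f1 = retrieve(ref_obs.downwelling, ref_obs.upwelling, selected_window("O2A", "FLD")).f_value
        assert abs(f3 - ref_obs.truth_o2a) < abs(f1 - ref_obs.truth_o2a)


class TestSfm:
    def test_exact_for_polynomial_truth(self):
        grid = uniform_grid(678.276, 696.276, 0.1)
        E = simulate_downwelling(10.0, (O2B_BAND,), grid)
        d = grid - 687.276
        r = 0.3 + 0.004 * d + 3e-4 * d**2
        f = 0.5 - 0.002 * d
        L = Spectrum(grid, E.values * r / np.pi + f, "radiance")
        w = selected_window("O2B", "SFM")
        i = np.argmin(np.abs(grid - 687.276))
        truth = 0.5 - 0.002 * (grid[i] - 687.276)
        assert abs(sfm(E, L, w).f_value - truth) / truth < 1e-8

    def test_zero_fluorescence_returns_zero(self, o2a_grid):
        E, L = make_pair(o2a_grid, r=0.4 + 0.001 * (o2a_grid - 760.0))
        assert abs(sfm(E, L, selected_window("O2A", "SFM")).f_value) < 1e-8

    def test_underdetermined_window_rejected(self):
        grid = uniform_grid(750.519, 775.519, 5.0)
        E, L = make_pair(grid)
        w = RetrievalWindow("SFM", "O2A", 760.519, 758.0, 763.0, degree_r=2, degree_f=1)
        with pytest.raises(ValueError, match="samples"):
            sfm(E, L, w)

    def test_collinear_design_warns(self, o2a_grid):
        E = Spectrum(o2a_grid, np.full_like(o2a_grid, 900.0), "irradiance")
        L = Spectrum(o2a_grid, E.values * 0.5 / np.pi + 0.3, "radiance")
        with pytest.warns(UserWarning, match="rank-deficient"):
            sfm(E, L, selected_window("O2A", "SFM"))

    def test_matches_normal_equations_oracle_on_toy_window(self):
        # 12-sample window; explicit Gram-matrix solve as independent oracle
        grid = uniform_grid(759.019, 764.519, 0.5)
        E = simulate_downwelling(0.0, (O2A_BAND,), grid)
        rng = np.random.default_rng(5)
        L = Spectrum(grid, E.values * 0.4 / np.pi + 0.6 + 0.01 * rng.standard_normal(grid.size), "radiance")
        w = RetrievalWindow("SFM", "O2A", 760.519, 759.019, 764.519, degree_r=1, degree_f=1)
        res = sfm(E, L, w)
        d = grid - 760.519
        e = E.values / np.pi
        design = np.column_stack([e, e * d, np.ones_like(d), d])
        coef = np.linalg.solve(design.T @ design, design.T @ L.values)
        assert np.allclose(res.coefficients, coef, atol=1e-8)


class TestAnchorsAndClosure:
    def test_anchors_snap_within_half_sample(self, ref_obs):
        wl = ref_obs.downwelling.wavelengths
        for w in bundled_windows():
            for anchor in (w.lambda_in, w.lambda_left, w.lambda_right):
                if anchor is not None:
                    i = np.argmin(np.abs(wl - anchor))
                    assert abs(wl[i] - anchor) < 0.2

    def test_far_anchor_rejected_on_coarse_grid(self):
        grid = uniform_grid(700.0, 800.0, 5.0)
        E, L = make_pair(grid)
        w = RetrievalWindow("FLD", "O2A", 760.519, 752.5)  # 2.5 nm from any sample
        with pytest.raises(ValueError, match="anchor"):
            fld(E, L, w)

    def test_noiseless_bare_land_retrieves_zero_where_assumptions_hold(self):
        grid = default_hires_grid()
        E = simulate_downwelling(30.0, DEFAULT_BANDS, grid)
        R, F = bare_land_scene(grid)
        L = compose_upwelling(E, R, F)
        # soil reflectance is linear, inside the SFM model class for both bands
        for band in ("O2A", "O2B"):
            assert abs(retrieve(E, L, selected_window(band, "SFM")).f_value) < 1e-8
        # FLD requires constant reflectance exactly
        L_const = Spectrum(grid, E.values * 0.3 / np.pi, "radiance")
        assert abs(retrieve(E, L_const, selected_window("O2A", "FLD")).f_value) < 1e-9

    def test_bias_ordering_on_reference_scene(self, ref_obs):
        biases = {
            alg: abs(
                retrieve(ref_obs.downwelling, ref_obs.upwelling, selected_window("O2A", alg)).f_value
                - ref_obs.truth_o2a
            )
            for alg in ("FLD", "3FLD", "SFM")
        }
        assert biases["FLD"] > biases["3FLD"]
        assert biases["FLD"] > biases["SFM"]


class TestEnsemble:
    def test_single_noiseless_realization(self, ref_obs):
        w = selected_window("O2A", "SFM")
        stats = retrieve_ensemble([ref_obs.downwelling], [ref_obs.upwelling], w, truth=ref_obs.truth_o2a)
        assert stats.sd == 0.0 and stats.n == 1
        single = retrieve(ref_obs.downwelling, ref_obs.upwelling, w)
        assert np.isclose(stats.bias, single.f_value - ref_obs.truth_o2a)

    def test_size_mismatch_rejected(self, ref_obs):
        w = selected_window("O2A", "FLD")
        with pytest.raises(ValueError):
            retrieve_ensemble([ref_obs.downwelling] * 2, [ref_obs.upwelling], w, truth=0.0)

    def test_candidate_tables_have_three_sets_per_algorithm(self):
        for band in ("O2A", "O2B"):
            for alg in ("FLD", "3FLD", "SFM"):
                assert len(candidate_windows(band, alg)) == 3
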