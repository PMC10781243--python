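"""Adaptive coherence-order maps and the TxMV-ADMAS beamformer."""

import numpy as np
import pytest

import pwbeam as pw
from pwbeam.admas import (
    REGION_BACKGROUND,
    REGION_I,
    REGION_II,
    REGION_III,
    AdmasThresholds,
    adaptive_p_map,
    alpha_map,
    alpha_pixel,
    beamform_txmv_admas,
    categorize_regions,
    gamma_pixel,
    gcf_map,
    gcf_pixel,
    median_filter_map,
    var_pixel,
)
from conftest import L_ANGLES


class TestGcf:
    def test_constant_vector_is_fully_coherent(self):
        assert gcf_pixel(np.ones(15) * (2 - 1j)) == pytest.approx(1.0)

    def test_off_band_tone_is_fully_incoherent(self):
        M, k = 16, 5
        z = np.exp(2j * np.pi * k * np.arange(M) / M)
        assert gcf_pixel(z, M0=1) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_vector_maps_to_zero(self):
        assert gcf_pixel(np.zeros(8)) == 0.0

    def test_matches_brute_force_dft_energy_ratio(self):
        rng = np.random.default_rng(0)
        M, M0 = 16, 2
        for _ in range(8):
            z = rng.standard_normal(M) + 1j * rng.standard_normal(M)
            # independent oracle: explicit DFT sums
            F = np.array(
                [np.sum(z * np.exp(-2j * np.pi * k * np.arange(M) / M)) for k in range(M)]
            )
            keep = [0] + list(range(1, M0 + 1)) + list(range(M - M0, M))
            brute = np.sum(np.abs(F[keep]) ** 2) / np.sum(np.abs(F) ** 2)
            assert gcf_pixel(z, M0) == pytest.approx(brute)

    def test_cutoff_must_be_below_half_band(self):
        with pytest.raises(ValueError):
            gcf_map(np.ones((2, 8)), M0=4)


class TestVar:
    def test_constant_magnitude_gives_zero(self):
        z = np.exp(1j * np.linspace(0, 3, 12))
        assert var_pixel(z) == pytest.approx(0.0)

    def test_single_bright_angle_is_maximally_dispersed(self):
        spike = np.zeros(10)
        spike[0] = 1.0
        others = np.full(10, 0.316)  # same total energy, spread out
        assert var_pixel(spike) > var_pixel(others)

    def test_matches_brute_force_variance(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(12) + 1j * rng.standard_normal(12)
        g = 1.7
        m = np.abs(z) * g
        brute = np.mean((m - m.mean()) ** 2)
        assert var_pixel(z, g) == pytest.approx(brute)


class TestRegions:
    def test_threshold_logic(self):
        th = AdmasThresholds()
        gcf = np.array([[0.5, 0.05, 0.15, 0.9]])
        var = np.array([[0.5, 0.01, 0.0005, 0.0005]])
        labels, reset = categorize_regions(gcf, var, th)
        assert labels[0, 0] == REGION_I  # var > 0.15
        assert labels[0, 1] == REGION_II  # gcf < 0.1
        assert labels[0, 2] == REGION_III  # gcf < 0.2 and var < 0.001
        assert labels[0, 3] == REGION_BACKGROUND
        assert np.allclose(reset[0], [0.0, 0.0, 0.0, 0.9])

    def test_precedence_and_reset_consistency(self):
        rng = np.random.default_rng(2)
        gcf = rng.uniform(0, 1, (20, 20))
        var = rng.uniform(0, 0.3, (20, 20))
        th = AdmasThresholds()
        labels, reset = categorize_regions(gcf, var, th)
        assert labels[(var > th.thv2)].min() == REGION_I == labels[(var > th.thv2)].max()
        flagged = labels != REGION_BACKGROUND
        assert np.all(reset[flagged] == 0)
        assert np.all(reset[~flagged] == gcf[~flagged])


class TestAlphaGamma:
    def test_alpha_analytic_values(self):
        assert alpha_pixel(0.3, 0.0) == 1.0
        assert alpha_pixel(0.0, 0.5) == 0.0
        assert alpha_pixel(0.0, 0.0) == 0.0  # region reset dominates 0^0
        assert alpha_pixel(0.5, 0.0625, m=4) == pytest.approx(0.5**0.5)

    def test_alpha_map_matches_pixel_version(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0, 1, 30)
        v = rng.uniform(0, 0.5, 30)
        g[::5] = 0.0
        got = alpha_map(g.reshape(5, 6), v.reshape(5, 6), 4).ravel()
        brute = [alpha_pixel(gi, vi, 4) for gi, vi in zip(g, v)]
        assert np.allclose(got, brute)

    def test_gamma_analytic_values(self):
        assert gamma_pixel(0.5) == pytest.approx(0.5)
        assert gamma_pixel(0.0) == pytest.approx(1 - 1 / (1 + np.e**9))
        assert gamma_pixel(1.0) == pytest.approx(1 / (1 + np.e**9))

    def test_gamma_strictly_decreasing(self):
        a = np.linspace(0, 1, 101)
        g = gamma_pixel(a)
        assert np.all(np.diff(g) < 0)


class TestMedianAndP:
    def test_constant_map_unchanged_and_spike_removed(self):
        m = np.full((9, 9), 0.4)
        assert np.allclose(median_filter_map(m, 3), m)
        m[4, 4] = 5.0
        out = median_filter_map(m, 3)
        assert out[4, 4] == pytest.approx(0.4)

    def test_matches_brute_force_sliding_median(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 1, (8, 16))
        k = 3
        pad = np.pad(m, k // 2, mode="edge")
        brute = np.empty_like(m)
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                brute[i, j] = np.median(pad[i : i + k, j : j + k])
        assert np.allclose(median_filter_map(m, k), brute)

    def test_adaptive_p_affine_map(self):
        assert adaptive_p_map(np.array(1.0), 1.0, 2.0) == pytest.approx(2.0)
        assert adaptive_p_map(np.array(0.0), 1.5, 3.0) == pytest.approx(1.5)
        assert adaptive_p_map(np.array(0.5), 1.0, 2.5) == pytest.approx(1.75)

    def test_p_monotone_decreasing_in_alpha(self):
        a = np.linspace(0, 1, 50)
        p = adaptive_p_map(gamma_pixel(a), 1.0, 2.0)
        assert np.all(np.diff(p) < 0)
        assert np.all((p >= 1.0) & (p <= 2.0))


class TestThresholdTypes:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            AdmasThresholds(thg1=0.3, thg2=0.2)
        with pytest.raises(ValueError):
            AdmasThresholds(thv1=0.2, thv2=0.1)
        with pytest.raises(ValueError):
            AdmasThresholds(p_min=2.0, p_max=1.0)
        with pytest.raises(ValueError):
            AdmasThresholds(median_kernel=4)


class TestAdmasBeamformer:
    def test_pmax_equals_pmin_1_collapses_to_txmv(self, random_cube):
        grid = pw.PixelGrid.regular((-2e-3, 2e-3), (20e-3, 21e-3), 1e-3, 2e-4)
        th = AdmasThresholds(p_min=1.0, p_max=1.0)
        a, maps = beamform_txmv_admas(random_cube, grid, thresholds=th, L=4)
        b = pw.beamform_txmv(random_cube, grid, L=4)
        assert np.allclose(maps.p_adaptive, 1.0)
        scale = np.abs(b.data).max()
        assert np.abs(a.data - b.data).max() <= 1e-10 * scale

    def test_speckle_p_stays_near_p_min(self, speckle_cube, speckle_grid):
        th = AdmasThresholds(p_min=1.0, p_max=2.0)
        _, maps = beamform_txmv_admas(speckle_cube, speckle_grid, thresholds=th, L=L_ANGLES)
        assert abs(np.median(maps.p_adaptive) - th.p_min) < 0.1

    def test_cyst_gets_higher_p_than_background(self, cyst_cube, cyst_grid, cyst_rois):
        cyst, bck = cyst_rois
        th = AdmasThresholds(p_min=1.0, p_max=2.0)
        img, maps = beamform_txmv_admas(cyst_cube, cyst_grid, thresholds=th, L=L_ANGLES)
        p_in = maps.p_adaptive[cyst.mask(cyst_grid)].mean()
        p_out = maps.p_adaptive[bck.mask(cyst_grid)].mean()
        assert p_in > p_out
        assert np.all(maps.gcf >= 0) and np.all(maps.gcf <= 1)
        assert np.all(maps.p_adaptive >= 1.0) and np.all(maps.p_adaptive <= 2.0)

    def test_admas_cnr_at_least_dmas_cnr(self, cyst_cube, cyst_grid, cyst_rois):
        from pwbeam.metrics import cnr, roi_values

        cyst, bck = cyst_rois
        th = AdmasThresholds(p_min=1.0, p_max=2.0)
        a, _ = beamform_txmv_admas(cyst_cube, cyst_grid, thresholds=th, L=L_ANGLES)
        d = pw.beamform_txmv_dmas(cyst_cube, cyst_grid, p=2.0, L=L_ANGLES)
        cnr_a = cnr(roi_values(a, cyst), roi_values(a, bck))
        cnr_d = cnr(roi_values(d, cyst), roi_values(d, bck))
        assert cnr_a >= cnr_d
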