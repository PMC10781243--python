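"""Whole-image beamformers: degeneracies, oracles and physical orderings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pwbeam as pw
from pwbeam.beamformers import dcr_snapshots, dmas_root_scale, tx_angle_stack
from pwbeam.metrics import fwhm_lateral, roi_values
from conftest import L_ANGLES


def rel_diff(a, b):
    scale = max(np.abs(a).max(), np.abs(b).max(), 1e-300)
    return np.abs(a - b).max() / scale


@pytest.fixture(scope="module")
def small_grid(random_cube):
    return pw.PixelGrid.regular((-3e-3, 3e-3), (20e-3, 21e-3), 1e-3, 2e-4)


class TestDegeneracies:
    def test_txmv_dmas_p1_equals_txmv(self, random_cube, small_grid):
        a = pw.beamform_txmv(random_cube, small_grid, L=4)
        b = pw.beamform_txmv_dmas(random_cube, small_grid, p=1.0, L=4)
        assert rel_diff(a.data, b.data) < 1e-10

    def test_txmv_L1_equals_cpwc(self, random_cube, small_grid):
        a = pw.beamform_cpwc(random_cube, small_grid)
        b = pw.beamform_txmv(random_cube, small_grid, L=1)
        assert rel_diff(a.data, b.data) < 1e-10

    def test_tx_dmas_p1_equals_cpwc(self, random_cube, small_grid):
        a = pw.beamform_cpwc(random_cube, small_grid)
        b = pw.beamform_tx_dmas(random_cube, small_grid, p=1.0)
        assert rel_diff(a.data, b.data) < 1e-10

    def test_rxmv_L1_equals_cpwc(self, random_cube, small_grid):
        a = pw.beamform_cpwc(random_cube, small_grid)
        b = pw.beamform_rxmv(random_cube, small_grid, L=1)
        assert rel_diff(a.data, b.data) < 1e-10

    def test_zero_cube_gives_zero_images(self, geometry, sequence, small_grid):
        cube = pw.AnalyticDataCube(
            np.zeros((sequence.n_angles, geometry.n_elements, 64), complex),
            geometry, sequence,
        )
        for name in ("cpwc", "txmv", "txmv-dmas", "tx-dmas"):
            fn = pw.get_beamformer(name)
            kw = {"L": 4} if name.startswith("txmv") else {}
            assert np.all(fn(cube, small_grid, **kw).data == 0)


class TestDistortionless:
    def test_constant_angle_array_passes_through_mv(self, geometry, sequence, small_grid):
        """A cube whose delayed data are constant per channel yields the
        constant through every MV pipeline (unity-gain constraint)."""
        c = 0.8 - 0.4j
        cube = pw.AnalyticDataCube(
            np.full((sequence.n_angles, geometry.n_elements, 1024), c),
            geometry, sequence,
        )
        Zs = tx_angle_stack(cube, small_grid)
        assert np.allclose(Zs, c)
        for img in (
            pw.beamform_txmv(cube, small_grid, L=4),
            pw.beamform_txmv_dmas(cube, small_grid, p=2.0, L=4),
            pw.beamform_rxmv(cube, small_grid),
            pw.beamform_dcr_mvdr(cube, small_grid),
        ):
            assert np.allclose(np.abs(img.data), abs(c), rtol=1e-8)


class TestBatchedConsistency:
    def test_angle_stack_matches_per_pixel_echo_matrix(self, point_cube):
        grid = pw.PixelGrid.regular((-1e-3, 1e-3), (24e-3, 25e-3), 1e-3, 5e-4)
        Zs = tx_angle_stack(point_cube, grid, 1.75)
        for iz, z in enumerate(grid.axial_z):
            for ix, x in enumerate(grid.lateral_x):
                X = pw.build_echo_matrix(point_cube, (x, z), 1.75)
                assert np.allclose(Zs[iz, ix], pw.channel_sum(X).z_values)


class TestDcrMvdr:
    def test_snapshots_match_brute_force_loop(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((8, 16)) + 1j * rng.standard_normal((8, 16))
        mask = np.ones(16, bool)
        mask[[3, 11]] = False
        X[:, ~mask] = 0
        snaps = dcr_snapshots(X, mask)
        active = np.flatnonzero(mask)
        assert snaps.shape == (active.size, 8)
        for row, j in enumerate(active):
            others = [jj for jj in active if jj != j]
            brute = X[:, others].mean(axis=1)
            assert np.allclose(snaps[row], brute)

    def test_identical_columns_collinear_with_cpwc(self):
        """Rank-one snapshot covariance: the output keeps the CPWC phase
        (it differs by a real positive loading-dependent scale)."""
        rng = np.random.default_rng(10)
        z = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        X = np.tile(z[:, None], (1, 8))
        snaps = dcr_snapshots(X, np.ones(8, bool))
        assert np.allclose(snaps, z[None, :])
        R = np.einsum("jm,jn->mn", snaps, snaps.conj()) / 8
        R += 1.0 * np.trace(R).real / 6 * np.eye(6)
        w0 = np.linalg.solve(R, np.ones(6))
        y = (w0 / w0.sum()).conj() @ z
        ratio = y / z.mean()
        assert ratio.imag == pytest.approx(0.0, abs=1e-10)
        assert ratio.real > 0

    def test_point_target_image_peaks_at_target(self, point_cube):
        grid = pw.PixelGrid.regular((-2e-3, 2e-3), (24e-3, 26e-3), 2e-4, 1e-4)
        img = pw.beamform_dcr_mvdr(point_cube, grid, delta=1.0)
        iz, ix = np.unravel_index(np.argmax(img.envelope), img.data.shape)
        assert abs(grid.lateral_x[ix]) <= 3e-4
        assert abs(grid.axial_z[iz] - 25e-3) <= 2e-4


class TestDmasScaling:
    def test_p1_identity_and_arithmetic(self):
        z = pw.TxAngleArray(np.array([4 * np.exp(1j * np.pi / 3), 0.0]))
        out = dmas_root_scale(z, 2.0)
        assert out.z_values[0] == pytest.approx(2 * np.exp(1j * np.pi / 3))
        assert out.z_values[1] == 0.0
        same = dmas_root_scale(z, 1.0)
        assert np.allclose(same.z_values, z.z_values)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10**6), st.floats(1.0, 4.0))
    def test_magnitude_law_and_phase_preserved(self, seed, p):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        out = dmas_root_scale(z, p)
        assert np.allclose(np.abs(out), np.abs(z) ** (1 / p))
        nz = np.abs(z) > 1e-12
        assert np.allclose(np.angle(out[nz]), np.angle(z[nz]))

    def test_single_angle_scaling_relation(self, geometry):
        """One nonzero angle: |tx-dmas| = |c| / M^p (root, mean over M,
        then p-th power)."""
        seq = pw.PlaneWaveSequence.symmetric(5, 4.0)
        data = np.zeros((5, geometry.n_elements, 1024), complex)
        c = 3.0 + 4.0j
        data[0] = c
        cube = pw.AnalyticDataCube(data, geometry, seq)
        grid = pw.PixelGrid.regular((-1e-3, 1e-3), (20e-3, 20.5e-3), 1e-3, 5e-4)
        for p in (1.0, 2.0):
            img = pw.beamform_tx_dmas(cube, grid, p=p)
            expected = abs(c) / 5**p
            assert np.allclose(np.abs(img.data), expected, rtol=1e-10)

    def test_global_scale_invariance_magnitude_law(self, random_cube, small_grid):
        """Scaling the cube by a complex constant scales every beamformer
        output magnitude by |c| (DMAS restores dimensionality)."""
        c = 0.5 * np.exp(1j * 0.7)
        scaled = pw.AnalyticDataCube(
            c * random_cube.data, random_cube.geometry, random_cube.sequence
        )
        for fn, kw in [
            (pw.beamform_cpwc, {}),
            (pw.beamform_txmv, {"L": 4}),
            (pw.beamform_txmv_dmas, {"L": 4, "p": 2.0}),
            (pw.beamform_tx_dmas, {"p": 2.0}),
        ]:
            a = fn(random_cube, small_grid, **kw)
            b = fn(scaled, small_grid, **kw)
            assert np.allclose(np.abs(b.data), abs(c) * np.abs(a.data), rtol=1e-8)


class TestPointResolution:
    def test_cpwc_peaks_at_the_scatterer(self, point_cube, point_grid):
        img = pw.beamform_cpwc(point_cube, point_grid)
        iz, ix = np.unravel_index(np.argmax(img.envelope), img.data.shape)
        assert abs(point_grid.lateral_x[ix]) <= point_grid.dx
        assert abs(point_grid.axial_z[iz] - 25e-3) <= 2 * point_grid.dz

    def test_single_angle_cube_is_das_image(self, point_cube, point_grid):
        sub = pw.AnalyticDataCube(
            point_cube.data[7:8],
            point_cube.geometry,
            pw.PlaneWaveSequence(point_cube.sequence.angles[7:8]),
        )
        img = pw.beamform_cpwc(sub, point_grid)
        assert np.isfinite(img.data).all() and img.envelope.max() > 0

    def test_resolution_ordering(self, point_cube, point_grid):
        """FWHM(TxMV-DMAS p=2) <= FWHM(TxMV) <= FWHM(CPWC)."""
        f_c = fwhm_lateral(pw.beamform_cpwc(point_cube, point_grid), 25e-3)
        f_t = fwhm_lateral(
            pw.beamform_txmv(point_cube, point_grid, L=L_ANGLES), 25e-3
        )
        f_d = fwhm_lateral(
            pw.beamform_txmv_dmas(point_cube, point_grid, p=2.0, L=L_ANGLES), 25e-3
        )
        assert f_d <= f_t <= f_c

    def test_rxmv_at_least_as_narrow_as_cpwc(self, point_cube):
        grid = pw.PixelGrid.regular((-3e-3, 3e-3), (24.5e-3, 25.5e-3), 7.4e-5, 7.4e-5)
        f_c = fwhm_lateral(pw.beamform_cpwc(point_cube, grid), 25e-3)
        f_r = fwhm_lateral(pw.beamform_rxmv(point_cube, grid), 25e-3)
        assert f_r <= f_c

    def test_L_exceeding_angle_count_rejected(self, point_cube, point_grid):
        with pytest.raises(ValueError):
            pw.beamform_txmv(point_cube, point_grid, L=99)


class TestCystContrast:
    def test_txmv_darkens_the_anechoic_cyst(self, cyst_cube, cyst_grid, cyst_rois):
        cyst, _ = cyst_rois
        a = pw.beamform_cpwc(cyst_cube, cyst_grid)
        b = pw.beamform_txmv(cyst_cube, cyst_grid, L=L_ANGLES)
        # compare on normalized envelopes so overall gain cancels
        am = roi_values(a, cyst).mean() / a.envelope.max()
        bm = roi_values(b, cyst).mean() / b.envelope.max()
        assert bm <= am

    def test_dmas_in_cyst_mean_monotone_in_p(self, cyst_cube, cyst_grid, cyst_rois):
        cyst, _ = cyst_rois
        means = []
        for p in (1.0, 1.5, 2.0, 2.5):
            img = pw.beamform_txmv_dmas(cyst_cube, cyst_grid, p=p, L=L_ANGLES)
            means.append(roi_values(img, cyst).mean())
        assert all(means[i] > means[i + 1] for i in range(len(means) - 1))


class TestRegistry:
    def test_known_and_unknown_names(self):
        assert pw.get_beamformer("cpwc") is pw.beamform_cpwc
        with pytest.raises(KeyError):
            pw.get_beamformer("nope")

    def test_p_below_one_rejected(self, random_cube, small_grid):
        with pytest.raises(ValueError):
            pw.beamform_tx_dmas(random_cube, small_grid, p=0.5)
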