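"""Phantom construction: brain geometry, ROA masks, HRF, design, noise."""

import numpy as np
import pytest
from scipy import ndimage

from awsom import phantom as ph
from awsom.exceptions import CalibrationError, DesignError, GridError, PlacementError


def brute_sphere_count(radius: float) -> int:
    """Independent triple-loop lattice enumeration of x^2+y^2+z^2 <= r^2."""
    r = int(np.ceil(radius))
    n = 0
    for x in range(-r, r + 1):
        for y in range(-r, r + 1):
            for z in range(-r, r + 1):
                if x * x + y * y + z * z <= radius * radius + 1e-9:
                    n += 1
    return n


class TestROAMasks:
    @pytest.mark.parametrize("radius", [0, 1, 2, 3, 4, 5, 6])
    def test_digital_sphere_matches_enumeration(self, radius):
        vox = ph._digital_sphere((20, 20, 20), float(radius))
        assert vox.shape[0] == brute_sphere_count(float(radius))

    def test_default_mask_sizes(self, grid48):
        masks = ph.make_roa_masks(grid48)
        assert [m.n_voxels for m in masks] == [33, 903, 257, 257]
        # the radius-0 degenerate case: a single voxel
        assert ph._digital_sphere((5, 5, 5), 0.0).shape[0] == 1

    def test_masks_connected_disjoint_inside_brain(self, grid48):
        masks = ph.make_roa_masks(grid48)
        _, brain = ph.make_baseline(grid48)
        union = np.zeros(grid48.shape, dtype=int)
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        for m in masks:
            dense = m.to_dense(grid48.shape)
            _, n_comp = ndimage.label(dense, structure=struct)
            assert n_comp == 1
            assert brain[dense].all()
            union += dense
        assert union.max() == 1

    def test_bad_placement_rejected(self, grid48):
        with pytest.raises(PlacementError):
            ph.make_roa_masks(grid48, centers=[(2, 2, 2), (30, 30, 20),
                                               (12, 28, 20), (28, 12, 20)])
        with pytest.raises(PlacementError):  # overlapping masks
            ph.make_roa_masks(grid48, centers=[(18, 18, 20), (20, 20, 20),
                                               (12, 28, 20), (28, 12, 20)])

    def test_irregular_target_count_is_honoured(self, grid48):
        masks = ph.make_roa_masks(grid48, irregular_target_count=500)
        assert masks[1].n_voxels == 500

    def test_heterogeneous_magnitudes_concentric(self, grid48):
        m = ph.make_roa_masks(grid48)[1].set_heterogeneous()
        assert sorted(np.unique(m.magnitude_pct)) == [1.5, 3.0, 6.0]
        d = np.linalg.norm(m.voxels - m.centroid(), axis=1)
        # innermost voxels carry the largest magnitude
        assert d[m.magnitude_pct == 6.0].mean() < d[m.magnitude_pct == 1.5].mean()


class TestBaseline:
    def test_uniform_constant_in_brain(self, grid48):
        baseline, brain = ph.make_baseline(grid48, "uniform")
        assert np.unique(baseline[brain]).size == 1
        assert (baseline[~brain] == 0).all()

    def test_shell_intensity_increases_towards_surface(self, grid48):
        baseline, brain = ph.make_baseline(grid48, "shell")
        r = ph._ellipsoid_radius(grid48)
        vals, radii = baseline[brain], r[brain]
        order = np.argsort(radii)
        # binned radial profile is strictly increasing in r (decreasing with
        # distance from the surface)
        bins = np.array_split(vals[order], 8)
        means = [b.mean() for b in bins]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_brain_volume_fraction(self, grid48):
        _, brain = ph.make_baseline(grid48)
        assert 0.30 <= brain.mean() <= 0.70

    def test_degenerate_grid_rejected(self):
        with pytest.raises(GridError):
            ph.GridSpec(shape=(8, 48, 48))


class TestHRF:
    @pytest.mark.parametrize("dt", [0.01, 0.05, 0.1])
    def test_landmarks(self, dt):
        h = ph.make_hrf(ph.HRFSpec(), dt_s=dt)
        t = np.arange(len(h)) * dt
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        assert abs(t[h.argmax()] - 4.8) <= dt + 1e-9
        assert abs(t[h.argmin()] - 8.4) <= dt + 1e-9
        assert h.min() < 0
        assert np.all(np.abs(h[t >= 19.99]) < 1e-3)

    def test_initial_dip_is_a_local_minimum(self, hrf_fine):
        t = np.arange(len(hrf_fine)) * 0.01
        window = (t > 0.4) & (t < 3.0)
        i = hrf_fine[window].argmin()
        assert abs(t[window][i] - 1.2) <= 0.05
        assert hrf_fine[window][i] < 0  # the dip undershoots baseline

    def test_bad_landmark_ordering_rejected(self):
        with pytest.raises(CalibrationError):
            ph.HRFSpec(t_dip_s=5.0)
        with pytest.raises(CalibrationError):
            ph.make_hrf(ph.HRFSpec(), dt_s=0.5)


class TestDesign:
    def test_default_regressor(self, grid48, hrf_fine):
        onsets, durations = ph.default_onsets(grid48)
        hrf = ph.make_hrf(ph.HRFSpec(), dt_s=0.1)
        reg = ph.make_design(onsets, durations, grid48, hrf)
        assert reg.shape == (grid48.n_volumes,)
        assert reg.max() == pytest.approx(1.0)
        excursions = np.diff(np.r_[0, (reg > 0.5).astype(int), 0])
        assert (excursions == 1).sum() == 8

    def test_zero_hrf_gives_zero_regressor(self, grid48):
        reg = ph.make_design([30.0], [0.0], grid48, np.zeros(200))
        assert not reg.any()

    def test_onset_beyond_scan_rejected(self, grid48):
        with pytest.raises(DesignError):
            ph.make_design([grid48.duration_s + 1.0], [0.0], grid48, np.ones(10))


class TestNoise:
    def test_seed_determinism(self, noiseless_phantom):
        spec = ph.NoiseSpec(level_pct=2.0, seed=42)
        a = ph.add_noise(noiseless_phantom, spec)
        b = ph.add_noise(noiseless_phantom, spec)
        assert np.array_equal(a.data, b.data)
        c = ph.add_noise(noiseless_phantom, ph.NoiseSpec(level_pct=2.0, seed=43))
        assert not np.array_equal(a.data, c.data)

    def test_target_tsnr_calibration(self, noisy_phantom):
        _, mean_tsnr = ph.measure_tsnr(noisy_phantom.data, noisy_phantom.brain_mask)
        assert mean_tsnr == pytest.approx(20.0, rel=0.05)

    def test_vanishing_level_approaches_identity(self, noiseless_phantom):
        noisy = ph.add_noise(noiseless_phantom, ph.NoiseSpec(level_pct=1e-6, seed=0))
        assert np.allclose(noisy.data, noiseless_phantom.data, atol=1e-3)

    def test_rician_offset_is_rayleigh_mean(self, noiseless_phantom):
        spec = ph.NoiseSpec(kind="rician", level_pct=4.0, seed=3)
        noisy = ph.add_noise(noiseless_phantom, spec)
        brain = noiseless_phantom.brain_mask
        sigma = noiseless_phantom.baseline[brain].mean() * spec.level_pct / 40.0
        shift = (noisy.data[brain] - noiseless_phantom.data[brain]).mean()
        assert shift == pytest.approx(sigma * np.sqrt(np.pi / 2.0), rel=0.01)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ph.NoiseSpec(kind="poisson")


class TestTSNR:
    def test_constant_series_flagged_infinite(self):
        series = np.ones((4, 4, 4, 20))
        tsnr, mean = ph.measure_tsnr(series, np.ones((4, 4, 4), bool))
        assert np.isinf(tsnr).all()
        assert np.isinf(mean)

    def test_known_ratio_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        series = 100.0 + 5.0 * rng.standard_normal((6, 6, 6, 2000))
        mask = np.ones((6, 6, 6), bool)
        _, mean = ph.measure_tsnr(series, mask)
        assert mean == pytest.approx(20.0, rel=0.03)
        _, scaled = ph.measure_tsnr(series * 7.5, mask)
        assert scaled == pytest.approx(mean, rel=1e-6)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(GridError):
            ph.measure_tsnr(np.ones((4, 4, 4, 5)), np.ones((4, 4, 4), bool))
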