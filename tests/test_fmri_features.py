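"""ALFF/fALFF/ReHo, map operations, ROI extraction and Fisher-z FC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nfbpredict.fmri_features import (VolumeSeries, alff, bandpass_timeseries,
                                      extract_roi_series, falff, fc_matrix,
                                      fwhm_to_sigma, gaussian_smooth,
                                      kendall_w, reho, z_standardize_map)

TR = 2.0


def explicit_dft_amplitudes(x, tr):
    """Brute-force one-sided amplitude spectrum after linear detrend."""
    x = np.asarray(x, dtype=float)
    n = x.size
    t = np.arange(n)
    slope, intercept = np.polyfit(t, x, 1)
    y = x - (slope * t + intercept)
    n_freq = n // 2 + 1
    amp = np.empty(n_freq)
    for k in range(n_freq):
        ang = -2j * np.pi * k * t / n
        amp[k] = 2.0 / n * abs(np.sum(y * np.exp(ang)))
    freqs = np.arange(n_freq) / (n * tr)
    return freqs, amp


class TestBandpass:
    def test_in_band_tone_passes(self):
        t = np.arange(400) * TR
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass_timeseries(x, TR)
        assert y[50:-50].std() >= 0.9 * x[50:-50].std()

    def test_out_of_band_tone_attenuated(self):
        t = np.arange(400) * TR
        x = np.sin(2 * np.pi * 0.2 * t)
        y = bandpass_timeseries(x, TR)
        assert y[50:-50].std() <= 0.1 * x[50:-50].std()

    def test_constant_series_maps_to_zero(self):
        y = bandpass_timeseries(np.full(100, 7.0), TR)
        np.testing.assert_allclose(y, 0.0, atol=1e-10)


class TestAlffFalff:
    def test_alff_linear_in_amplitude(self):
        t = np.arange(120) * TR
        x = np.sin(2 * np.pi * 0.04 * t)
        assert alff(2 * x, TR) == pytest.approx(2 * alff(x, TR), rel=1e-12)

    def test_in_band_tone_raises_alff_over_noise(self, rng):
        noise = rng.standard_normal(120)
        t = np.arange(120) * TR
        assert alff(noise + np.sin(2 * np.pi * 0.04 * t), TR) > alff(noise, TR)

    def test_alff_matches_explicit_dft_oracle(self, rng):
        x = rng.standard_normal(90)
        freqs, amp = explicit_dft_amplitudes(x, TR)
        sel = (freqs >= 0.01) & (freqs <= 0.08) & (freqs > 0)
        assert alff(x, TR) == pytest.approx(amp[sel].mean(), rel=1e-10)

    def test_falff_matches_explicit_dft_oracle(self, rng):
        x = rng.standard_normal(90)
        freqs, amp = explicit_dft_amplitudes(x, TR)
        sel = (freqs >= 0.01) & (freqs <= 0.08) & (freqs > 0)
        want = amp[sel].sum() / amp[freqs > 0].sum()
        assert falff(x, TR) == pytest.approx(want, rel=1e-10)

    def test_falff_of_pure_in_band_tone_near_one(self):
        # detrending a finite tone leaks a little amplitude broadband,
        # so "~1" means >0.9 under the mean-amplitude convention
        t = np.arange(500) * TR
        assert falff(np.sin(2 * np.pi * 0.04 * t), TR) > 0.9

    def test_falff_of_out_of_band_tone_near_zero(self):
        t = np.arange(500) * TR
        assert falff(np.sin(2 * np.pi * 0.2 * t), TR) < 0.05

    def test_falff_scale_invariant(self, rng):
        x = rng.standard_normal(100)
        assert falff(x, TR) == pytest.approx(falff(13.0 * x, TR), rel=1e-12)


class TestKendallW:
    def test_identical_series_give_one(self, rng):
        x = np.tile(rng.standard_normal(50), (27, 1))
        assert kendall_w(x) == pytest.approx(1.0)

    def test_hand_computed_three_series_toy(self):
        # ranks: [1,2,3], [1,3,2], [2,1,3] -> rank sums [4,6,8], S=8
        # W = 12*8 / (9*(27-3)) = 4/9
        x = np.array([[10.0, 20.0, 30.0],
                      [1.0, 3.0, 2.0],
                      [5.0, 4.0, 6.0]])
        assert kendall_w(x) == pytest.approx(4.0 / 9.0)

    def test_independent_series_give_small_w(self, rng):
        x = rng.standard_normal((27, 100))
        assert kendall_w(x) < 0.15

    def test_tie_correction_on_constant_judge(self):
        # one fully tied judge contributes nothing; W of the rest governs
        x = np.array([[1.0, 2.0, 3.0, 4.0],
                      [1.0, 2.0, 3.0, 4.0],
                      [5.0, 5.0, 5.0, 5.0]])
        assert 0.0 < kendall_w(x) <= 1.0


class TestReho:
    def test_identical_volume_series_give_w_one(self, rng):
        series = np.tile(rng.standard_normal(30), (6, 6, 6, 1))
        mask = np.ones((6, 6, 6), dtype=bool)
        w = reho(series, mask)
        # corners have 8-member neighborhoods (< 9 minimum) and read 0
        interior = np.zeros_like(mask)
        interior[1:-1, 1:-1, 1:-1] = True
        np.testing.assert_allclose(w[interior], 1.0, atol=1e-12)
        assert w[0, 0, 0] == 0.0
        w_all = reho(series, mask, min_neighbors=1)
        np.testing.assert_allclose(w_all, 1.0, atol=1e-12)

    def test_matches_per_voxel_kendall_w(self, rng):
        shape = (5, 5, 5)
        series = rng.standard_normal(shape + (20,))
        mask = np.ones(shape, dtype=bool)
        w = reho(series, mask, min_neighbors=1)
        # brute force at an interior and a corner voxel
        for vox in [(2, 2, 2), (0, 0, 0)]:
            neigh = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        i, j, k = vox[0] + di, vox[1] + dj, vox[2] + dk
                        if 0 <= i < 5 and 0 <= j < 5 and 0 <= k < 5:
                            neigh.append(series[i, j, k])
            assert w[vox] == pytest.approx(kendall_w(np.array(neigh)), rel=1e-12)

    def test_min_neighbors_zeroes_isolated_voxels(self, rng):
        shape = (5, 5, 5)
        series = rng.standard_normal(shape + (20,))
        mask = np.zeros(shape, dtype=bool)
        mask[2, 2, 2] = True  # neighborhood of size 1 < 9
        w = reho(series, mask)
        assert w[2, 2, 2] == 0.0

    def test_too_few_timepoints_raises(self):
        with pytest.raises(ValueError):
            reho(np.zeros((3, 3, 3, 1)), np.ones((3, 3, 3), dtype=bool))


class TestMapOps:
    def test_z_standardize_moments(self, rng):
        vol = rng.standard_normal((8, 8, 8)) * 4 + 10
        mask = rng.random((8, 8, 8)) > 0.3
        z = z_standardize_map(vol, mask)
        assert abs(z[mask].mean()) < 1e-10
        assert z[mask].std() == pytest.approx(1.0)
        assert (z[~mask] == 0).all()

    def test_z_standardize_affine_invariant(self, rng):
        vol = rng.standard_normal((6, 6, 6))
        mask = np.ones((6, 6, 6), dtype=bool)
        z1 = z_standardize_map(vol, mask)
        z2 = z_standardize_map(3.0 * vol - 5.0, mask)
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_z_standardize_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            z_standardize_map(np.ones((4, 4, 4)), np.ones((4, 4, 4), dtype=bool))

    def test_fwhm_six_mm_at_three_mm_voxels(self):
        assert fwhm_to_sigma(6.0, 3.0) == pytest.approx(0.84932, abs=1e-4)

    def test_smoothing_preserves_interior_sum(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        sm = gaussian_smooth(vol, fwhm_mm=6.0, voxel_mm=3.0)
        assert sm.sum() == pytest.approx(1.0, rel=1e-6)
        assert sm[7, 7, 7] == sm.max()


def _volume(data, tr=TR, mask=None, voxel=3.0):
    mask = np.ones(data.shape[:3], dtype=bool) if mask is None else mask
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return VolumeSeries(data=data, tr=tr, mask=mask, affine=affine)


class TestRoiExtraction:
    def test_single_voxel_sphere_returns_that_series(self, rng):
        data = rng.standard_normal((6, 6, 6, 20))
        vol = _volume(data)
        roi = pd.DataFrame([{"name": "a", "x": 9.0, "y": 9.0, "z": 9.0,
                             "radius": 1.0}])
        out = extract_roi_series(vol, roi)
        np.testing.assert_allclose(out.loc["a"].to_numpy(), data[3, 3, 3])

    def test_uniform_volume_gives_identical_series(self):
        data = np.ones((8, 8, 8, 10)) * 5.0
        vol = _volume(data)
        roi = pd.DataFrame([
            {"name": "a", "x": 9.0, "y": 9.0, "z": 9.0, "radius": 6.0},
            {"name": "b", "x": 15.0, "y": 15.0, "z": 15.0, "radius": 6.0}])
        out = extract_roi_series(vol, roi)
        np.testing.assert_allclose(out.loc["a"], out.loc["b"])

    def test_eight_mm_sphere_on_three_mm_grid_has_81_voxels(self):
        # brute-force count of voxel centres within 8 mm of an on-grid centre
        count = sum(1 for i in range(-3, 4) for j in range(-3, 4)
                    for k in range(-3, 4)
                    if 9 * (i * i + j * j + k * k) <= 64)
        assert count == 81
        data = np.zeros((15, 15, 15, 3))
        data[7, 7, 7, :] = 1.0
        vol = _volume(data)
        roi = pd.DataFrame([{"name": "c", "x": 21.0, "y": 21.0, "z": 21.0,
                             "radius": 8.0}])
        out = extract_roi_series(vol, roi)
        assert out.loc["c"].iloc[0] == pytest.approx(1.0 / 81)

    def test_empty_sphere_names_roi(self):
        vol = _volume(np.zeros((5, 5, 5, 4)))
        roi = pd.DataFrame([{"name": "nowhere", "x": 500.0, "y": 0.0, "z": 0.0,
                             "radius": 2.0}])
        with pytest.raises(ValueError, match="nowhere"):
            extract_roi_series(vol, roi)


class TestFcMatrix:
    def test_closed_form_values(self):
        # construct two series with exact Pearson r = 0.5
        n = 400
        rng = np.random.default_rng(0)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        b /= b.std()
        y = 0.5 * a + np.sqrt(1 - 0.25) * b
        z = fc_matrix(np.vstack([a, y]))
        assert z.iloc[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-10)
        assert z.iloc[0, 1] == pytest.approx(0.5493, abs=1e-4)
        assert z.iloc[0, 0] == 0.0

    def test_identical_pair_clipped_with_warning(self, rng):
        a = rng.standard_normal(50)
        with pytest.warns(RuntimeWarning, match="clipped"):
            z = fc_matrix(np.vstack([a, a]))
        assert np.isfinite(z.iloc[0, 1])
        assert z.iloc[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_zero_variance_series_raises(self):
        x = np.vstack([np.ones(30), np.arange(30.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            fc_matrix(x)

    def test_roi_permutation_equivariance(self, rng):
        x = rng.standard_normal((5, 60))
        z = fc_matrix(x).to_numpy()
        perm = [3, 1, 4, 0, 2]
        zp = fc_matrix(x[perm]).to_numpy()
        np.testing.assert_allclose(zp, z[np.ix_(perm, perm)], atol=1e-12)

    def test_symmetry_and_finite(self, rng):
        z = fc_matrix(rng.standard_normal((6, 80))).to_numpy()
        np.testing.assert_allclose(z, z.T)
        assert np.isfinite(z).all()


class TestVolumeSeries:
    def test_mask_shape_checked(self):
        with pytest.raises(ValueError, match="mask"):
            VolumeSeries(data=np.zeros((4, 4, 4, 5)), tr=2.0,
                         mask=np.ones((3, 3, 3), dtype=bool), affine=np.eye(4))

    def test_tr_positive(self):
        with pytest.raises(ValueError, match="TR"):
            VolumeSeries(data=np.zeros((4, 4, 4, 5)), tr=0.0,
                         mask=np.ones((4, 4, 4), dtype=bool), affine=np.eye(4))
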