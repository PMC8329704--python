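"""Synthetic cohort generator: determinism, copula control, planted effects."""

import numpy as np
import pytest
from scipy import stats

from nfbpredict.fmri_features import alff, z_standardize_map
from nfbpredict.synthgen import (CohortConfig, PlantedEffect, _cluster_voxels,
                                 _ellipsoid_mask, generate_cohort,
                                 generate_latent_cohort,
                                 generate_split_effect_cohort, synth_fmri,
                                 synth_morphometry, synth_nfb_run,
                                 synth_resting_eeg, spearman_to_gaussian)
from tests.conftest import small_cohort_config


class TestConfig:
    def test_counts_validated(self):
        with pytest.raises(ValueError):
            CohortConfig(n_participants=0)
        with pytest.raises(ValueError):
            CohortConfig(run_duration_s=-1)

    def test_effect_validation(self):
        with pytest.raises(ValueError):
            PlantedEffect("eeg_power", {"roi": "left central"}, 1.0)
        with pytest.raises(ValueError):
            PlantedEffect("unknown", {}, 0.5)
        with pytest.raises(ValueError):
            PlantedEffect("alff", {}, 0.5, noise_sd=-1)


class TestDeterminism:
    def test_same_seed_gives_identical_cohort(self):
        cfg = small_cohort_config(n_participants=3, eeg_duration_s=3.0,
                                  n_volumes=30)
        d1, g1 = generate_cohort(cfg)
        d2, g2 = generate_cohort(cfg)
        np.testing.assert_array_equal(g1.true_slopes, g2.true_slopes)
        np.testing.assert_array_equal(d1.nfb_runs[0][0][0], d2.nfb_runs[0][0][0])
        np.testing.assert_array_equal(d1.resting_eeg[1]["eyes_open"][0],
                                      d2.resting_eeg[1]["eyes_open"][0])
        np.testing.assert_array_equal(d1.fmri[2].data, d2.fmri[2].data)
        np.testing.assert_array_equal(d1.gmv[0], d2.gmv[0])

    def test_nfb_run_deterministic(self):
        a = synth_nfb_run(0.1, 2, 250, 4.0, np.random.default_rng(9))
        b = synth_nfb_run(0.1, 2, 250, 4.0, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestLatentCopula:
    def test_spearman_converges_to_target(self):
        cfg = CohortConfig(
            n_participants=2000,
            effect_map=(PlantedEffect("eeg_power", {"roi": "left central"}, 0.6),),
            seed=42)
        tab, gt = generate_latent_cohort(cfg)
        rho = stats.spearmanr(tab.iloc[:, 0], gt.true_slopes)[0]
        assert rho == pytest.approx(0.6, abs=0.05)

    def test_gaussian_mapping_closed_form(self):
        assert spearman_to_gaussian(0.0) == 0.0
        assert spearman_to_gaussian(0.5) == pytest.approx(2 * np.sin(np.pi / 12))

    def test_noise_attenuates_correlation(self):
        mk = lambda sd: CohortConfig(
            n_participants=1500,
            effect_map=(PlantedEffect("alff", {"center": (8, 8, 8), "radius": 2}, 0.7,
                                      noise_sd=sd),),
            seed=11)
        t0, g0 = generate_latent_cohort(mk(0.0))
        t2, g2 = generate_latent_cohort(mk(2.0))
        r0 = stats.spearmanr(t0.iloc[:, 0], g0.true_slopes)[0]
        r2 = stats.spearmanr(t2.iloc[:, 0], g2.true_slopes)[0]
        assert r0 > r2 + 0.1


class TestNfbRuns:
    def test_record_counts_match_protocol(self):
        cfg = small_cohort_config(n_participants=2, n_sessions=3,
                                  runs_per_session=12, run_duration_s=11.0,
                                  eeg_duration_s=2.0, n_volumes=20,
                                  grid_shape=(8, 8, 8), n_rois=4,
                                  effect_map=())
        ds, _ = generate_cohort(cfg)
        assert len(ds.nfb_runs) == 2
        assert len(ds.nfb_runs[0]) == 3
        assert all(len(s) == 12 for s in ds.nfb_runs[0])

    def test_zero_slope_gives_flat_band_power(self):
        rng = np.random.default_rng(0)
        powers = []
        for r in range(5):
            sig = synth_nfb_run(0.0, r, 250, 4.0, rng, noise_sd=0.0)
            powers.append(np.mean(sig ** 2))  # total power ~ band power here
        assert np.ptp(powers) < 1e-6 * np.mean(powers)

    def test_positive_slope_monotone_when_noiseless(self):
        rng = np.random.default_rng(0)
        powers = [np.mean(synth_nfb_run(0.2, r, 250, 4.0, rng, noise_sd=0.0) ** 2)
                  for r in range(1, 6)]
        assert np.all(np.diff(powers) > 0)

    def test_negative_duration_raises(self):
        with pytest.raises(ValueError):
            synth_nfb_run(0.1, 0, 250, -5.0)

    def test_power_floor_keeps_amplitude_positive(self):
        sig = synth_nfb_run(-10.0, 5, 250, 2.0, np.random.default_rng(0),
                            noise_sd=0.0)
        assert np.all(np.isfinite(sig)) and sig.std() > 0


class TestRestingEeg:
    def test_shape_and_names(self):
        sig, names = synth_resting_eeg(64, fs=250, duration_s=2.0,
                                       rng=np.random.default_rng(0))
        assert sig.shape == (64, 500)
        assert len(set(names)) == 64

    def test_missing_required_channels_rejected(self):
        with pytest.raises(ValueError, match="missing required"):
            synth_resting_eeg(["C3", "C5"], rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="at least"):
            synth_resting_eeg(10, rng=np.random.default_rng(0))

    def test_latent_ordering_preserved_in_smr_amplitude(self):
        # same seed, two latent levels: the higher latent yields more SMR power
        from nfbpredict.eeg_features import preprocess_resting, welch_power, relative_band_power
        from nfbpredict.synthgen import REQUIRED_EEG_CHANNELS
        powers = []
        for lat in (-1.0, 1.0):
            sig, names = synth_resting_eeg(
                list(REQUIRED_EEG_CHANNELS), fs=250, duration_s=4.0,
                rng=np.random.default_rng(3), smr_latents={"C3": lat})
            ep = preprocess_resting(sig, 250)
            f, psd = welch_power(ep, 250, nfft=256)
            rp = relative_band_power(f, psd, (12, 15), (1, 100))
            powers.append(np.median(rp[:, names.index("C3")]))
        assert powers[1] > powers[0]

    def test_doubled_alpha_amplitude_raises_alpha_power(self):
        from nfbpredict.eeg_features import preprocess_resting, welch_power, relative_band_power
        from nfbpredict.synthgen import REQUIRED_EEG_CHANNELS
        vals = []
        for amp in (1.5, 3.0):
            sig, names = synth_resting_eeg(
                list(REQUIRED_EEG_CHANNELS), fs=250, duration_s=4.0,
                rng=np.random.default_rng(4), amp_overrides={("Cz", "alpha"): amp})
            ep = preprocess_resting(sig, 250)
            f, psd = welch_power(ep, 250, nfft=256)
            rp = relative_band_power(f, psd, (8, 12), (1, 100))
            vals.append(np.median(rp[:, names.index("Cz")]))
        assert vals[1] > vals[0]


class TestFmri:
    def test_planted_alff_cluster_exceeds_background(self):
        shape = (10, 10, 10)
        mask = _ellipsoid_mask(shape)
        vox = _cluster_voxels((5, 5, 5), 1.6, shape)
        data, mask = synth_fmri(shape, 80, 2.0, np.random.default_rng(0),
                                mask=mask, alff_effects=[(vox, 3.0)],
                                noise_sd=0.5)
        amap = alff(data, 2.0, axis=-1)
        inside = amap[tuple(vox.T)].mean()
        outside_mask = mask.copy()
        outside_mask[tuple(vox.T)] = False
        assert inside > amap[outside_mask].mean()

    def test_fc_weight_monotonically_raises_roi_correlation(self):
        shape = (12, 12, 12)
        mask = np.ones(shape, dtype=bool)
        va = _cluster_voxels((3, 3, 3), 1.6, shape)
        vb = _cluster_voxels((8, 8, 8), 1.6, shape)
        cors = []
        for w in (0.0, 0.8, 2.5):
            data, _ = synth_fmri(shape, 100, 2.0, np.random.default_rng(5),
                                 mask=mask, fc_effects=[(va, vb, w)])
            sa = data[tuple(va.T)].mean(axis=0)
            sb = data[tuple(vb.T)].mean(axis=0)
            cors.append(stats.pearsonr(sa, sb)[0])
        assert cors[0] < cors[1] < cors[2]

    def test_no_effects_z_map_standard(self):
        data, mask = synth_fmri((8, 8, 8), 50, 2.0, np.random.default_rng(1))
        amap = z_standardize_map(alff(data, 2.0, axis=-1), mask)
        assert abs(amap[mask].mean()) < 1e-10
        assert amap[mask].std() == pytest.approx(1.0)

    def test_cluster_outside_mask_raises(self):
        shape = (8, 8, 8)
        mask = _ellipsoid_mask(shape)
        vox = _cluster_voxels((0, 0, 0), 1.4, shape)  # corner, outside ellipsoid
        with pytest.raises(ValueError, match="mask"):
            synth_fmri(shape, 30, 2.0, np.random.default_rng(0), mask=mask,
                       alff_effects=[(vox, 2.0)])


class TestMorphometry:
    def test_cluster_offset_orders_participants(self):
        shape = (8, 8, 8)
        vox = _cluster_voxels((4, 4, 4), 1.4, shape)
        latents = [-2.0, 0.0, 2.0]
        means = []
        for lat in latents:
            vol = synth_morphometry(shape, np.random.default_rng(7),
                                    clusters=[(vox, 0.3 * lat, 0.0)])
            means.append(vol[tuple(vox.T)].mean())
        assert means[0] < means[1] < means[2]

    def test_opposite_sign_clusters_recovered_by_glm(self):
        # two disjoint planted clusters with opposite signs, n=60, strong effect
        import pandas as pd
        from nfbpredict.screening import permutation_glm_map
        shape = (12, 12, 12)
        mask = np.ones(shape, dtype=bool)
        vox_pos = _cluster_voxels((3, 3, 3), 2.0, shape)
        vox_neg = _cluster_voxels((8, 8, 8), 2.0, shape)
        rng = np.random.default_rng(21)
        n = 60
        li = rng.standard_normal(n)
        maps = np.stack([
            synth_morphometry(shape, rng, mask=mask,
                              clusters=[(vox_pos, 0.5 * li[i], 0.0),
                                        (vox_neg, -0.5 * li[i], 0.0)])
            for i in range(n)])
        cov = pd.DataFrame({"age": rng.normal(23, 2, n),
                            "sex": rng.choice(["M", "F"], n)})
        pos, neg = permutation_glm_map(maps, li, cov, mask=mask, n_perm=300,
                                       min_cluster=20, seed=0)
        assert len(pos.clusters) >= 1 and len(neg.clusters) >= 1
        found_pos = set(map(tuple, pos.clusters[0].voxels))
        found_neg = set(map(tuple, neg.clusters[0].voxels))
        assert len(found_pos & set(map(tuple, vox_pos))) / len(vox_pos) >= 0.8
        assert len(found_neg & set(map(tuple, vox_neg))) / len(vox_neg) >= 0.8


class TestGroundTruthHygiene:
    def test_ground_truth_not_part_of_dataset(self, small_cohort):
        ds, gt = small_cohort
        assert not hasattr(ds, "true_slopes")
        assert gt.true_slopes.shape == (ds.config.n_participants,)
        d = gt.to_dict()
        assert set(d) == {"true_slopes", "latents", "effects"}

    def test_unknown_roi_effect_raises(self):
        cfg = small_cohort_config(
            n_participants=2, eeg_duration_s=2.0, n_volumes=20,
            effect_map=(PlantedEffect("eeg_power", {"roi": "nowhere"}, 0.5),))
        with pytest.raises(ValueError, match="unknown scalp ROI"):
            generate_cohort(cfg)

    def test_fc_effect_with_unknown_roi_raises(self):
        cfg = small_cohort_config(
            n_participants=2, eeg_duration_s=2.0, n_volumes=20,
            effect_map=(PlantedEffect("fc", {"edge": ("roi000", "missing")}, 0.5),))
        with pytest.raises(ValueError, match="missing"):
            generate_cohort(cfg)


class TestSplitEffectCohort:
    def test_structure_and_signal(self):
        tables, li = generate_split_effect_cohort(n_participants=300, seed=0)
        assert set(tables) == {"eeg", "smri", "alff", "fc"}
        assert all(t.shape == (300, 3) for t in tables.values())
        # every modality correlates with LI, none perfectly
        for t in tables.values():
            r = abs(stats.pearsonr(t.iloc[:, 0], li)[0])
            assert 0.2 < r < 0.8
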