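"""Motion QC, temporal filtering, seed FC mapping and cluster thresholding."""

import numpy as np
import pandas as pd
import pytest

from covnet.fmri import (
    BoldDataset,
    cluster_threshold,
    detrend_and_bandpass,
    group_compare_maps,
    motion_qc,
    seed_fc_map,
)
from covnet.synthetic import MOTION_COLUMNS, FmriSimSpec, generate_fmri_dataset


def motion_frame(n=20):
    frame = pd.DataFrame(0.0, index=range(n), columns=list(MOTION_COLUMNS))
    frame["volume"] = np.arange(n)
    return frame


class TestMotionQC:
    def test_translation_over_one_mm_fails(self):
        motion = motion_frame()
        motion.loc[3, "tx_mm"] = 1.2
        result = motion_qc(motion)
        assert not result.passed
        assert list(result.offending.index) == [3]

    def test_within_limits_passes(self):
        motion = motion_frame()
        motion.loc[:, ["tx_mm", "ty_mm", "tz_mm"]] = 0.5
        motion.loc[:, ["rx_deg", "ry_deg", "rz_deg"]] = 1.0
        assert motion_qc(motion).passed

    def test_rotation_over_two_fails(self):
        motion = motion_frame()
        motion.loc[7, "ry_deg"] = 2.5
        assert not motion_qc(motion).passed

    def test_limits_are_exclusive(self):
        motion = motion_frame()
        motion.loc[0, "tz_mm"] = 1.0  # exactly at the limit: not "exceeded"
        motion.loc[1, "rz_deg"] = 2.0
        assert motion_qc(motion).passed

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            motion_qc(pd.DataFrame({"tx_mm": [0.0]}))


class TestDetrendAndBandpass:
    def test_constant_series_zeroed(self):
        out = detrend_and_bandpass(np.full(600, 7.3), repetition_time=1.0)
        assert np.max(np.abs(out)) < 1e-10

    def test_linear_ramp_removed(self):
        ramp = np.linspace(0.0, 50.0, 600)
        out = detrend_and_bandpass(ramp, repetition_time=1.0)
        assert np.max(np.abs(out)) < 1e-8 * 50.0

    def test_fft_passband_and_stopband(self):
        t = np.arange(600)
        freqs = np.fft.rfftfreq(600, d=1.0)

        def amplitude_at(series, f):
            spectrum = np.abs(np.fft.rfft(series)) / len(series) * 2
            return spectrum[np.argmin(np.abs(freqs - f))]

        inside = np.sin(2 * np.pi * 0.05 * t)
        outside = np.sin(2 * np.pi * 0.2 * t)
        assert amplitude_at(detrend_and_bandpass(inside, 1.0), 0.05) >= 0.9
        assert amplitude_at(detrend_and_bandpass(outside, 1.0), 0.2) <= 0.1

    def test_offset_suppressed(self, rng):
        # a +100 baseline leaves only a small residual relative to the signal sd
        out = detrend_and_bandpass(rng.normal(size=600) + 100.0, repetition_time=1.0)
        assert abs(out.mean()) < 0.05 * out.std()

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            detrend_and_bandpass(np.zeros(100), repetition_time=6.0)  # Nyquist < 0.1 Hz

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="10 timepoints"):
            detrend_and_bandpass(np.zeros(5), repetition_time=1.0)


def toy_dataset(r=0.6, seed=0, n_timepoints=300):
    seed_voxels = np.array([[1, 1, 1], [1, 2, 1], [2, 1, 1], [2, 2, 1]])
    cluster = np.array([[5, y, z] for y in range(2, 7) for z in range(0, 4)])
    spec = FmriSimSpec(
        volume_shape=(8, 8, 4),
        n_timepoints=n_timepoints,
        seed_voxels=seed_voxels,
        cluster_specs=((cluster, r),) if r is not None else (),
        seed=seed,
    )
    sim = generate_fmri_dataset(spec)
    return BoldDataset(
        data=sim.data, repetition_time=1.0,
        brain_mask=sim.brain_mask, seed_mask=sim.seed_mask,
    ), cluster


class TestSeedFCMap:
    def test_seed_voxel_self_correlation_clipped_finite(self):
        dataset, _ = toy_dataset()
        fc = seed_fc_map(dataset)
        # every seed voxel carries the reference signal itself
        assert fc.r_map[1, 1, 1] == pytest.approx(1.0, abs=1e-9)
        assert np.isfinite(fc.z_map[1, 1, 1])

    def test_null_voxels_weakly_correlated(self):
        dataset, cluster = toy_dataset(r=None)
        fc = seed_fc_map(dataset)
        null_r = fc.r_map[5, 0, 0]  # independent-noise voxel, T=300
        assert abs(null_r) < 0.15

    def test_planted_cluster_recovered(self):
        dataset, cluster = toy_dataset(r=0.6)
        fc = seed_fc_map(dataset)
        mean_r = float(np.mean(fc.r_map[tuple(cluster.T)]))
        assert 0.5 <= mean_r <= 0.7

    def test_invariant_to_positive_affine_rescaling(self):
        dataset, _ = toy_dataset()
        fc1 = seed_fc_map(dataset)
        dataset.data[5, 5, 2] = 3.0 * dataset.data[5, 5, 2] + 40.0
        fc2 = seed_fc_map(dataset)
        assert fc2.r_map[5, 5, 2] == pytest.approx(fc1.r_map[5, 5, 2], abs=1e-9)

    def test_split_seed_halves_average_to_full_reference(self):
        dataset, _ = toy_dataset()
        full = seed_fc_map(dataset, band=None)
        half1 = dataset.seed_mask.copy()
        half2 = dataset.seed_mask.copy()
        half1[2] = False  # drop two of four seed voxels from each half
        half2[1] = False
        d1 = BoldDataset(data=dataset.data, repetition_time=1.0,
                         brain_mask=dataset.brain_mask, seed_mask=half1)
        d2 = BoldDataset(data=dataset.data, repetition_time=1.0,
                         brain_mask=dataset.brain_mask, seed_mask=half2)
        # equal-sized halves: averaging the two references reproduces the full one,
        # so a probe voxel's correlation is unchanged
        r_full = full.r_map[6, 6, 3]
        fc1 = seed_fc_map(d1, band=None)
        fc2 = seed_fc_map(d2, band=None)
        assert (fc1.r_map[6, 6, 3] + fc2.r_map[6, 6, 3]) / 2 == pytest.approx(r_full, abs=1e-9)

    def test_zero_variance_seed_rejected(self):
        data = np.random.default_rng(0).normal(size=(4, 4, 4, 50))
        seed_mask = np.zeros((4, 4, 4), bool)
        seed_mask[0, 0, 0] = True
        data[0, 0, 0] = 5.0
        dataset = BoldDataset(data=data, repetition_time=1.0,
                              brain_mask=np.ones((4, 4, 4), bool), seed_mask=seed_mask)
        with pytest.raises(ValueError, match="zero variance"):
            seed_fc_map(dataset, band=None)

    def test_seed_outside_brain_rejected(self):
        data = np.zeros((4, 4, 4, 20))
        brain = np.zeros((4, 4, 4), bool)
        brain[:2] = True
        seed = np.zeros((4, 4, 4), bool)
        seed[3, 3, 3] = True
        with pytest.raises(ValueError, match="inside the brain"):
            BoldDataset(data=data, repetition_time=1.0, brain_mask=brain, seed_mask=seed)


class TestGroupCompareMaps:
    def test_identical_maps_give_p_one(self, rng):
        mask = np.ones((4, 4, 2), bool)
        template = rng.normal(size=(4, 4, 2))
        maps = {"A": [template] * 3, "B": [template] * 3}
        stats = group_compare_maps(maps, mask)
        np.testing.assert_allclose(stats.f_p_map[mask], 1.0)
        np.testing.assert_allclose(stats.pair_p_maps[("A", "B")][mask], 1.0)

    def test_null_p_values_approximately_uniform(self, rng):
        mask = np.ones((10, 10, 5), bool)
        maps = {
            "A": [rng.normal(size=(10, 10, 5)) for _ in range(8)],
            "B": [rng.normal(size=(10, 10, 5)) for _ in range(8)],
        }
        stats = group_compare_maps(maps, mask)
        frac = float((stats.pair_p_maps[("A", "B")][mask] < 0.05).mean())
        # binomial 95% band around 0.05 with 500 voxels
        from scipy.stats import binom
        lo, hi = binom.interval(0.95, 500, 0.05)
        assert lo / 500 <= frac <= hi / 500

    def test_shifted_voxels_detected(self, rng):
        mask = np.ones((6, 6, 3), bool)
        maps_a = [rng.normal(size=(6, 6, 3)) for _ in range(8)]
        maps_b = [rng.normal(size=(6, 6, 3)) for _ in range(8)]
        for m in maps_a:
            m[0, 0, 0] += 2.0  # 2 SD shift
        stats = group_compare_maps({"A": maps_a, "B": maps_b}, mask)
        assert stats.pair_p_maps[("A", "B")][0, 0, 0] < 0.05
        assert stats.pair_t_maps[("A", "B")][0, 0, 0] > 0

    def test_too_few_maps_rejected(self, rng):
        mask = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError, match="at least 3"):
            group_compare_maps(
                {"A": [rng.normal(size=(2, 2, 2))] * 2,
                 "B": [rng.normal(size=(2, 2, 2))] * 3},
                mask,
            )

    def test_shape_mismatch_rejected(self, rng):
        mask = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError, match="shape"):
            group_compare_maps(
                {"A": [rng.normal(size=(3, 2, 2))] * 3,
                 "B": [rng.normal(size=(2, 2, 2))] * 3},
                mask,
            )


class TestClusterThreshold:
    def make_maps(self, shape=(20, 20, 10)):
        p_map = np.ones(shape)
        stat_map = np.zeros(shape)
        return p_map, stat_map

    def test_no_suprathreshold_voxels(self):
        p_map, stat_map = self.make_maps()
        assert len(cluster_threshold(p_map, stat_map)) == 0

    def test_single_blob_above_extent_survives(self):
        p_map, stat_map = self.make_maps()
        p_map[2:7, 2:6, 2:5] = 1e-4  # 5*4*3 = 60 voxels
        stat_map[2:7, 2:6, 2:5] = 4.0
        result = cluster_threshold(p_map, stat_map, voxel_p=0.005, min_cluster_size=50)
        assert len(result) == 1
        assert result.clusters[0].size == 60
        assert result.clusters[0].sign == 1

    def test_extent_threshold_is_strict(self):
        # blobs of sizes 10, 49, 50, 51 at extent ">50": only 51 survives
        p_map = np.ones((60, 12, 12))
        stat_map = np.zeros((60, 12, 12))
        for row, size in enumerate((10, 49, 50, 51)):
            p_map[:size, 3 * row, 0] = 1e-4
            stat_map[:size, 3 * row, 0] = 5.0
        result = cluster_threshold(p_map, stat_map, voxel_p=0.005, min_cluster_size=50)
        assert [c.size for c in result.clusters] == [51]

    def test_signs_split_components(self):
        p_map, stat_map = self.make_maps()
        p_map[0:4, 0:4, 0:4] = 1e-4
        stat_map[0:2, 0:4, 0:4] = 3.0
        stat_map[2:4, 0:4, 0:4] = -3.0
        result = cluster_threshold(p_map, stat_map, min_cluster_size=10)
        signs = sorted(c.sign for c in result.clusters)
        assert signs == [-1, 1]
        assert all(c.size == 32 for c in result.clusters)

    def test_peak_location_reported(self):
        p_map, stat_map = self.make_maps()
        p_map[2:7, 2:6, 2:5] = 1e-4
        stat_map[2:7, 2:6, 2:5] = 4.0
        stat_map[4, 3, 3] = 9.0
        result = cluster_threshold(p_map, stat_map, min_cluster_size=10)
        assert result.clusters[0].peak_location == (4, 3, 3)
        assert result.clusters[0].peak_stat == 9.0

    def test_connectivity_rule_changes_merging(self):
        # a diagonal voxel run is edge-connected (18) but not face-connected (6)
        p_map = np.ones((8, 8, 3))
        stat_map = np.zeros((8, 8, 3))
        for i in range(6):
            p_map[i, i, 1] = 1e-4
            stat_map[i, i, 1] = 2.0
        merged = cluster_threshold(p_map, stat_map, min_cluster_size=4, connectivity=18)
        split = cluster_threshold(p_map, stat_map, min_cluster_size=4, connectivity=6)
        assert len(merged) == 1 and merged.clusters[0].size == 6
        assert len(split) == 0
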