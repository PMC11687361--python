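import numpy as np
import pytest
from scipy import stats

from conftest import make_series
from leadpop.detection import (
    global_cutoff,
    DetectionConfig,
    channel_outlier_fraction,
    detect,
    global_outliers,
    local_bad_segments,
    merge_outliers_into_regions,
)
from leadpop.pipeline import run_detection
from leadpop.records import ConfigurationError, NoAnalyzableDataError

CFG = DetectionConfig()


class TestLocalRule:
    def test_constant_series_has_no_bad_segments(self):
        series = make_series(np.full(300, 0.8))
        assert not local_bad_segments(series, CFG).any()

    def test_deep_dip_is_bad(self):
        vals = np.full(300, 0.8)
        vals[150] = 0.1  # window median 0.8 → threshold 0.4
        bad = local_bad_segments(make_series(vals), CFG)
        assert bad[150] and bad.sum() == 1

    def test_moderate_dip_is_not_bad(self):
        vals = np.full(300, 0.8)
        vals[150] = 0.5
        assert not local_bad_segments(make_series(vals), CFG).any()

    def test_boundary_exactly_half_median_is_not_bad(self):
        vals = np.full(300, 0.8)
        vals[150] = 0.4  # exactly local_fraction * median: strict <
        assert not local_bad_segments(make_series(vals), CFG).any()

    def test_boundary_just_below_half_median_is_bad(self):
        vals = np.full(300, 0.8)
        vals[150] = np.nextafter(0.4, 0.0)
        assert local_bad_segments(make_series(vals), CFG)[150]

    def test_undefined_segments_never_flagged(self):
        vals = np.full(300, 0.8)
        vals[10:20] = np.nan
        vals[150] = 0.1
        bad = local_bad_segments(make_series(vals), CFG)
        assert not bad[10:20].any() and bad[150]

    def test_negative_median_clamps_threshold_to_zero(self):
        vals = np.full(300, -0.5)
        vals[150] = -0.9
        bad = local_bad_segments(make_series(vals), CFG)
        # threshold clamped at 0: every negative value is below it
        assert bad.all()

    def test_all_undefined_raises(self):
        with pytest.raises(NoAnalyzableDataError):
            local_bad_segments(make_series(np.full(100, np.nan)), CFG)

    def test_center_window_membership_variant(self):
        vals = np.full(300, 0.8)
        vals[150] = 0.1
        cfg = DetectionConfig(window_membership="center")
        bad = local_bad_segments(make_series(vals), cfg)
        assert bad[150] and bad.sum() == 1


class TestGlobalRule:
    def test_constant_pool_threshold(self):
        vals = np.full(200, 0.8)
        vals[50], vals[60] = 0.1, 0.3  # tau = 0.25 * 0.8 = 0.2
        bad = np.zeros(200, dtype=bool)
        out = global_outliers(make_series(vals), bad, CFG)
        assert out[50] and not out[60]
        assert out.sum() == 1

    def test_bad_segments_always_outliers(self):
        vals = np.full(200, 0.8)
        bad = np.zeros(200, dtype=bool)
        bad[[3, 77]] = True  # regardless of their (high) values
        out = global_outliers(make_series(vals), bad, CFG)
        assert out[3] and out[77]

    def test_percentile_uses_linear_interpolation(self):
        # pool {0.4, 0.6, 0.8, 1.0}: p75 = 0.85 by linear interpolation
        # between closest ranks; cross-checked against an independent
        # implementation, so tau = 0.25 * 0.85 = 0.2125
        pool = np.array([0.4, 0.6, 0.8, 1.0])
        expected_p75 = stats.scoreatpercentile(pool, 75)
        assert expected_p75 == pytest.approx(0.85)
        tau = global_cutoff(pool, CFG)
        assert tau == pytest.approx(0.25 * expected_p75)
        # a good segment just under the cutoff is an outlier, just above not
        vals = np.concatenate([np.full(60, 0.8), [tau - 1e-4, tau + 1e-4]])
        out = global_outliers(make_series(vals), np.zeros(62, bool), CFG)
        # the two probes barely move p75 of the pool; recompute honestly
        tau_full = global_cutoff(vals, CFG)
        assert out[60] == (vals[60] < tau_full)
        assert out[61] == (vals[61] < tau_full)

    def test_empty_good_pool_marks_all_defined(self):
        vals = np.full(50, 0.5)
        bad = np.ones(50, dtype=bool)
        with pytest.warns(UserWarning, match="empty good pool"):
            out = global_outliers(make_series(vals), bad, CFG)
        assert out.all()


class TestMergeRule:
    def test_gap_just_under_300_merges(self):
        outliers = np.zeros(600, dtype=bool)
        outliers[[100, 399]] = True  # gap 299 < 300
        regions, merged = merge_outliers_into_regions(outliers, CFG, "C3")
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_s, r.end_s, r.n_segments) == (100, 399, 300)
        assert r.source == "merged"
        assert merged[100:400].all()

    def test_gap_exactly_300_does_not_merge(self):
        outliers = np.zeros(600, dtype=bool)
        outliers[[100, 400]] = True  # gap exactly 300: strict <
        regions, merged = merge_outliers_into_regions(outliers, CFG, "C3")
        assert [(r.start_s, r.end_s) for r in regions] == [(100, 100), (400, 400)]
        assert merged.sum() == 2

    def test_no_outliers_no_regions(self):
        regions, merged = merge_outliers_into_regions(np.zeros(100, bool), CFG)
        assert regions == [] and not merged.any()

    def test_chained_merging(self):
        outliers = np.zeros(1000, dtype=bool)
        outliers[[0, 250, 500, 950]] = True
        regions, _ = merge_outliers_into_regions(outliers, CFG, "C3")
        assert [(r.start_s, r.end_s) for r in regions] == [(0, 500), (950, 950)]


class TestChannelFraction:
    def test_exactly_five_percent_is_not_over(self):
        outliers = np.zeros(10_000, dtype=bool)
        outliers[:500] = True
        frac = channel_outlier_fraction(outliers, np.ones(10_000, bool))
        assert frac == pytest.approx(0.05)
        assert not frac > CFG.channel_exclude_fraction

    def test_one_over_five_percent_is_over(self):
        outliers = np.zeros(10_000, dtype=bool)
        outliers[:501] = True
        frac = channel_outlier_fraction(outliers, np.ones(10_000, bool))
        assert frac == pytest.approx(0.0501)
        assert frac > CFG.channel_exclude_fraction

    def test_no_outliers_gives_zero(self):
        assert channel_outlier_fraction(
            np.zeros(100, bool), np.ones(100, bool)
        ) == 0.0

    def test_denominator_excludes_unanalyzable(self):
        outliers = np.zeros(100, dtype=bool)
        outliers[:10] = True
        analyzable = np.ones(100, dtype=bool)
        analyzable[50:] = False
        assert channel_outlier_fraction(outliers, analyzable) == pytest.approx(0.2)

    def test_zero_denominator_raises(self):
        with pytest.raises(NoAnalyzableDataError):
            channel_outlier_fraction(np.zeros(10, bool), np.zeros(10, bool))


class TestDetect:
    def test_clean_record_no_exclusions(self, short_clean_night):
        recording, _ = short_clean_night
        run = run_detection(recording)
        res = run.result
        assert res.excluded_channels == []
        assert res.n_iterations == 1
        for ch, frac in res.per_channel_outlier_fraction.items():
            assert frac < 0.005, ch

    def test_pop_noise_channel_excluded_first_iteration(self, short_pop_night):
        recording, truth = short_pop_night
        run = run_detection(recording)
        res = run.result
        assert res.excluded_channels == [(1, "C3")]
        # excluded channel still receives region annotations
        assert res.regions["C3"], "C3 should carry artifact regions"
        covered = sum(r.n_segments for r in res.regions["C3"])
        assert covered >= 0.9 * truth.flags["C3"].sum()
        for ch in ("F3", "F4", "C4", "O1", "O2"):
            assert res.per_channel_outlier_fraction[ch] <= 0.05

    def test_fewer_than_two_channels_raises(self, short_clean_night):
        recording, _ = short_clean_night
        from leadpop.preprocessing import preprocess
        from leadpop.spectral import spectrograms_for
        pre = preprocess(recording)
        specs = spectrograms_for(
            {"C3": pre.channels["C3"]}, pre.sampling_rate
        )
        with pytest.raises(NoAnalyzableDataError):
            detect(pre, specs)

    def test_detection_is_deterministic(self, short_pop_night):
        recording, _ = short_pop_night
        a = run_detection(recording).result
        b = run_detection(recording).result
        assert a.regions == b.regions
        assert a.excluded_channels == b.excluded_channels

    def test_stage_separate_mode_runs_and_flags_artifact(self, short_pop_night):
        recording, truth = short_pop_night
        cfg = DetectionConfig(stage_mode="nrem_rem_separate")
        res = run_detection(recording, detection_cfg=cfg).result
        assert ("C3" in {ch for _, ch in res.excluded_channels})
        covered = sum(r.n_segments for r in res.regions["C3"])
        assert covered >= 0.8 * truth.flags["C3"].sum()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            DetectionConfig(local_fraction=0.0)
        with pytest.raises(ConfigurationError):
            DetectionConfig(merge_gap_s=0)
        with pytest.raises(ConfigurationError):
            DetectionConfig(global_percentile=100.0)
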