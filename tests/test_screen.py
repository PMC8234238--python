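"""Baseline-vs-challenge feature screening rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fcmid.screen import (
    FeatureTimecourse,
    ScreenConfig,
    baseline_fold_filter,
    classify_kinetics,
    consecutive_run_filter,
    intersect_animals,
    normalize_timecourse,
    profile_correlation,
    resolve_floor,
    screen_animal,
    screen_study,
)
from fcmid.io import features_by_animal, timecourses_from_frames
from fcmid.simulate import simulate_study


def tc(intensities, times=None, **kw):
    intensities = np.asarray(intensities, dtype=float)
    if times is None:
        n = len(intensities)
        times = np.concatenate([[-12.0, -6.0], np.linspace(2, 60, n - 2)])
    defaults = dict(
        feature_id="f", neutral_mass=366.24063, retention_time=9.1,
        polarity="negative", animal="A",
    )
    defaults.update(kw)
    return FeatureTimecourse(times=np.asarray(times, float), intensities=intensities, **defaults)


class TestTimecourseValidation:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            FeatureTimecourse("f", 366.0, 9.0, "negative", np.array([0.0, 1.0]), np.array([1.0]))

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            tc([1, 2, 3, 4, 5], times=[-2, -1, 5, 3, 10])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            tc([1, -2, 3, 4, 5])

    def test_epoch_masks_split_at_administration(self):
        f = tc([1, 2, 3, 4, 5], times=[-2, -1, 1, 2, 3])
        assert f.bc_mask.sum() == 2 and f.ac_mask.sum() == 3


class TestNormalize:
    def test_maximum_becomes_one(self):
        f = normalize_timecourse(tc([10, 20, 40, 80, 20]))
        assert f.intensities.max() == 1.0
        assert f.intensities[0] == pytest.approx(0.125)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_timecourse(tc([0, 0, 0, 0, 0]))

    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=5, max_size=20))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_preserves_intensity_ratios(self, values):
        f = normalize_timecourse(tc(values))
        ratio = np.asarray(values) / max(values)
        assert np.allclose(f.intensities, ratio)


class TestFoldFilter:
    def test_tenfold_elevation_retained(self):
        f = tc([100, 100, 1500, 1200, 1100])
        (d,) = baseline_fold_filter([f], ScreenConfig(), floor=1.0)
        assert d.retained and d.reason == "fold-ok"
        assert d.fold == pytest.approx(15.0)

    def test_subthreshold_elevation_excluded(self):
        f = tc([100, 100, 900, 800, 700])
        (d,) = baseline_fold_filter([f], ScreenConfig(), floor=1.0)
        assert not d.retained and d.reason == "below-fold-threshold"

    def test_zero_baseline_compared_to_floor(self):
        f = tc([0, 0, 500, 400, 450])
        (d,) = baseline_fold_filter([f], ScreenConfig(), floor=10.0)
        assert d.retained
        assert d.fold == pytest.approx(50.0)

    def test_floor_defaults_to_one_percent_of_median_nonzero(self):
        feats = [tc([0, 0, 100, 100, 100]), tc([0, 0, 300, 300, 300], feature_id="g")]
        floor = resolve_floor(feats, ScreenConfig())
        # nonzero intensities are 100×3 and 300×3 → median 200
        assert floor == pytest.approx(0.01 * 200.0)

    @given(st.floats(min_value=1.01, max_value=50.0))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_raising_threshold_never_adds_retentions(self, thresh):
        feats = [
            tc([100, 90, 1500, 1300, 1200]),
            tc([100, 90, 600, 550, 500], feature_id="g"),
            tc([0, 0, 30, 25, 20], feature_id="h"),
        ]
        lo = baseline_fold_filter(feats, ScreenConfig(fold_threshold=thresh), floor=1.0)
        hi = baseline_fold_filter(feats, ScreenConfig(fold_threshold=thresh * 1.5), floor=1.0)
        for a, b in zip(lo, hi):
            assert a.retained or not b.retained


class TestRunFilter:
    def test_sustained_run_retained(self):
        f = tc([0, 0, 900, 1000, 950, 100, 50], times=[-2, -1, 2, 4, 6, 30, 60])
        (d,) = consecutive_run_filter([f], ScreenConfig())
        assert d.retained and d.run_length == 3

    def test_alternating_spikes_excluded(self):
        f = tc([0, 0, 500, 0, 500, 0, 500], times=[-2, -1, 2, 4, 6, 8, 10])
        (d,) = consecutive_run_filter([f], ScreenConfig(min_run=3))
        assert not d.retained and d.reason == "non-consecutive-high-values"
        assert d.run_length == 1

    def test_single_spike_excluded(self):
        f = tc([0, 0, 0, 1e6, 0, 0, 0], times=[-2, -1, 2, 4, 6, 8, 10])
        (d,) = consecutive_run_filter([f], ScreenConfig())
        assert not d.retained

    def test_run_length_matches_run_length_encoding_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            vals = rng.uniform(0, 1000, size=n)
            times = np.concatenate([[-1.0], np.sort(rng.uniform(0.1, 70, size=n))])
            f = tc(np.concatenate([[0.0], vals]), times=times)
            (d,) = consecutive_run_filter([f], ScreenConfig())
            high = vals >= 0.5 * vals.max()
            best = 0
            for k, g in __import__("itertools").groupby(high):
                if k:
                    best = max(best, len(list(g)))
            assert d.run_length == best

    @given(st.integers(min_value=2, max_value=8))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_raising_min_run_never_adds_retentions(self, run):
        f = tc([0, 0, 900, 1000, 950, 940, 100], times=[-2, -1, 2, 4, 6, 8, 10])
        lo = consecutive_run_filter([f], ScreenConfig(min_run=run))[0]
        hi = consecutive_run_filter([f], ScreenConfig(min_run=run + 1))[0]
        assert lo.retained or not hi.retained


class TestKinetics:
    def test_delayed_broad_profile_is_metabolite_like(self):
        times = np.array([-2, -1, 1, 3, 6, 10, 16, 24, 36, 48, 60, 72], float)
        v = np.array([0, 0, 30, 120, 700, 1000, 900, 650, 350, 150, 60, 30], float)
        k = classify_kinetics(tc(v, times=times))
        assert k.label == "metabolite-like"
        assert k.peak_time == pytest.approx(10.0)

    def test_early_sharp_profile_is_parent_like(self):
        times = np.array([-2, -1, 1, 3, 6, 10, 16, 24, 36, 48, 60, 72], float)
        v = np.array([0, 0, 1000, 800, 400, 150, 40, 10, 5, 3, 2, 1], float)
        k = classify_kinetics(tc(v, times=times))
        assert k.label == "parent-like"
        assert k.peak_time == pytest.approx(1.0)

    def test_flat_elevated_profile_unclassified(self):
        times = np.array([-2, -1, 1, 12, 24, 36, 48, 60, 72], float)
        v = np.array([0, 0, 900, 950, 900, 920, 910, 930, 905], float)
        assert classify_kinetics(tc(v, times=times)).label == "unclassified"

    def test_all_zero_after_administration_unclassified(self):
        f = tc([10, 10, 0, 0, 0], times=[-2, -1, 1, 2, 3])
        assert classify_kinetics(f).label == "unclassified"

    def test_simulated_compounds_mostly_match_their_generating_kinetics(self, default_config):
        study = simulate_study(default_config)
        feats = timecourses_from_frames(study.features, study.metadata)
        truth = study.truth.set_index("feature_id")
        correct = total = 0
        for f in feats:
            kind = truth.loc[f.feature_id, "kind"]
            if kind in ("parent", "metabolite"):
                total += 1
                correct += classify_kinetics(f).label == f"{kind}-like"
        assert total == 12
        # the two kernel families overlap, so a small error rate is expected
        assert correct >= 10


class TestProfileCorrelation:
    def test_identical_series_fully_correlated(self):
        f = tc([0, 0, 100, 500, 300, 100, 50], times=[-2, -1, 2, 6, 12, 24, 48])
        r, n = profile_correlation(f, f.times, f.intensities)
        assert r == pytest.approx(1.0)
        assert n == 7

    def test_inverted_series_anticorrelated(self):
        f = tc([0, 0, 100, 500, 300, 100, 50], times=[-2, -1, 2, 6, 12, 24, 48])
        r, _ = profile_correlation(f, f.times, 1000 - f.intensities)
        assert r == pytest.approx(-1.0)

    def test_too_few_shared_times_gives_nan(self):
        f = tc([0, 0, 100, 500, 300], times=[-2, -1, 2, 6, 12])
        r, n = profile_correlation(f, np.array([2.0, 6.0]), np.array([1.0, 2.0]))
        assert n == 2 and np.isnan(r)

    def test_eia_tracks_generating_metabolite(self, small_config):
        study = simulate_study(small_config)
        animal = small_config.animals[0]
        thf_id = study.truth.query("animal == @animal and name == 'THF'")["feature_id"].iloc[0]
        feats = timecourses_from_frames(study.features, study.metadata)
        f = next(x for x in feats if x.feature_id == thf_id)
        eia = study.eia_series.query("animal == @animal and assay == '50c'").sort_values("time_h")
        r, n = profile_correlation(f, eia["time_h"].to_numpy(), eia["response_ng_g"].to_numpy())
        assert n >= 10
        assert r > 0.9


class TestEndToEnd:
    def test_all_seeded_compounds_recovered_and_decoys_rejected(self, small_config):
        study = simulate_study(small_config)
        feats = timecourses_from_frames(study.features, study.metadata)
        reports, intersection = screen_study(features_by_animal(feats))
        truth = study.truth.set_index("feature_id")
        for animal, rep in reports.items():
            retained = rep[rep["retained"]]
            kinds = truth.loc[retained["feature_id"], "kind"]
            assert set(kinds) <= {"parent", "metabolite"}
            assert len(retained) == len(small_config.metabolites)
        assert len(intersection) == len(small_config.metabolites)

    def test_screen_report_order_insensitive(self, small_config):
        study = simulate_study(small_config)
        feats = timecourses_from_frames(study.features, study.metadata)
        grouped = features_by_animal(feats)
        animal = small_config.animals[0]
        fwd = screen_animal(grouped[animal])
        rev = screen_animal(list(reversed(grouped[animal])))
        fwd = fwd.sort_values("feature_id").reset_index(drop=True)
        rev = rev.sort_values("feature_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_intersection_requires_matching_polarity(self):
        def mk(animal, pol):
            return pd.DataFrame([{
                "feature_id": f"{animal}_F0", "animal": animal,
                "neutral_mass": 366.24063, "rt_min": 9.1, "polarity": pol,
                "retained": True, "reason": "retained", "fold": 20.0,
                "run_length": 5, "kinetic_class": "metabolite-like",
            }])
        both = intersect_animals({"A": mk("A", "negative"), "B": mk("B", "negative")})
        assert len(both) == 1
        none = intersect_animals({"A": mk("A", "negative"), "B": mk("B", "positive")})
        assert len(none) == 0


class TestConfigValidation:
    def test_fold_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            ScreenConfig(fold_threshold=1.0)

    def test_min_run_of_one_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(min_run=1)
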