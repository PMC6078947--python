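"""Sliding-window decoding, permutation significance, window selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import compdrop as cd
from compdrop import ConfigurationError, EpochSet
from compdrop.containers import DecodingCurve


def toy_epochs(data, sfreq=512.0, t0=0.0, metadata=None):
    data = np.asarray(data, dtype=float)
    times = t0 + np.arange(data.shape[2]) * 1000.0 / sfreq
    if metadata is None:
        metadata = pd.DataFrame(index=range(data.shape[0]))
    return EpochSet(data=data, times=times, sfreq=sfreq, metadata=metadata)


def blobs(n_per_class=40, d=8, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, d))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1, 0] += sep
    return X, y


class TestSlidingWindowFeatures:
    def test_constant_epoch_gives_constant_features(self):
        epochs = toy_epochs(np.full((3, 4, 256), 2.5))
        feats = cd.sliding_window_features(epochs)
        assert np.allclose(feats.features, 2.5)

    def test_linear_ramp_feature_is_window_midpoint_value(self):
        sfreq = 500.0  # 2 ms spacing: 25 samples fill a 50 ms window evenly
        n = 250
        slope = 0.004  # per ms
        epochs = toy_epochs((slope * np.arange(n) * 2.0)[None, None, :], sfreq=sfreq)
        feats = cd.sliding_window_features(epochs, window_ms=50.0, step_ms=20.0)
        # mean of an arithmetic sequence over [t, t+50) = value at the
        # midpoint of the covered samples: t + (24/2)*2 ms = t + 24 ms
        expected = slope * (feats.start_times + 24.0)
        assert np.allclose(feats.features[0, :, 0], expected)

    def test_matches_explicit_index_enumeration_oracle(self, s1_data):
        epochs, _ = s1_data
        feats = cd.sliding_window_features(epochs, window_ms=50.0, step_ms=20.0)
        for k, t0 in enumerate(feats.start_times):
            idx = [i for i, t in enumerate(epochs.times) if t0 <= t < t0 + 50.0]
            oracle = epochs.data[:, :, idx].mean(axis=2)
            assert np.allclose(feats.features[:, k, :], oracle)

    def test_windows_past_epoch_end_excluded(self):
        epochs = toy_epochs(np.zeros((1, 2, 128)), sfreq=512.0)  # 250 ms epoch
        feats = cd.sliding_window_features(epochs, window_ms=50.0, step_ms=20.0)
        assert feats.start_times[-1] + 50.0 <= 250.0 + 1e-9


class TestCrossvalDecode:
    def test_separable_blobs_decoded_above_95pct(self):
        X, y = blobs()
        assert cd.crossval_decode(X, y, seed=1) >= 0.95

    def test_shuffled_labels_near_chance(self):
        X, y = blobs(seed=2)
        rng = np.random.default_rng(3)
        accs = [cd.crossval_decode(X, rng.permutation(y), seed=4) for _ in range(20)]
        # binomial 99% band around 0.5 for n=80 trials, averaged over repeats
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_channel_permutation_invariance(self):
        X, y = blobs(seed=5)
        perm = np.random.default_rng(6).permutation(X.shape[1])
        assert cd.crossval_decode(X, y, seed=7) == cd.crossval_decode(X[:, perm], y, seed=7)

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ConfigurationError):
            cd.crossval_decode(X, np.zeros(10, dtype=int))

    def test_minority_class_smaller_than_folds_rejected(self):
        X = np.zeros((10, 3))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ConfigurationError):
            cd.crossval_decode(X, y, n_folds=5)


class TestWithinSubjectPermutation:
    def test_observed_above_all_permutations_gives_add_one_floor(self):
        X, y = blobs(sep=10.0, seed=8)
        res = cd.within_subject_permutation_p(X, y, n_perm=100, seed=9)
        assert res.p == pytest.approx(1.0 / 101.0)

    def test_p_in_unit_interval_and_never_zero(self):
        X, y = blobs(sep=0.0, seed=10)
        res = cd.within_subject_permutation_p(X, y, n_perm=20, seed=11)
        assert 0.0 < res.p <= 1.0

    def test_accuracy_below_null_median_gives_large_p(self):
        # constant features decode at whatever the fold split allows; make
        # observed worse than typical null by using anti-correlated labels
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 4))
        y = rng.integers(0, 2, 60)
        res = cd.within_subject_permutation_p(X, y, n_perm=60, seed=13)
        if res.accuracy < np.median(res.null_accuracies):
            assert res.p > 0.5


class TestGroupSignificance:
    def test_strong_consistent_subjects_significant(self):
        rng = np.random.default_rng(0)
        # all subjects at the permutation floor, with jitter to avoid the
        # degenerate zero-variance t statistic
        p = np.clip(rng.normal(1.0 / 101.0, 0.002, size=(12, 10)), 1e-4, 1.0)
        mask, group_p = cd.group_significance(p, alpha=0.001, n_perm=100)
        assert mask.all()

    def test_null_p_half_not_significant(self):
        p = np.full((8, 10), 0.5)
        mask, group_p = cd.group_significance(p, alpha=0.001, n_perm=100)
        assert not mask.any()
        assert np.all(group_p >= 0.5)  # z = 0 for every subject

    def test_bonferroni_threshold_divides_by_n_timepoints(self):
        rng = np.random.default_rng(1)
        p = np.clip(rng.normal(0.02, 0.005, size=(10, 55)), 1e-4, 1.0)
        mask, group_p = cd.group_significance(p, alpha=0.001, n_perm=100)
        assert np.array_equal(mask, group_p < 0.001 / 55)

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            cd.group_significance(np.full((2, 5), 0.2))

    def test_matches_direct_formula_evaluation(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 0.99, size=(9, 7))
        _, group_p = cd.group_significance(p, n_perm=100)
        z = stats.norm.ppf(1 - np.clip(p, 1 / 101, 100 / 101))
        for t in range(7):
            expect = stats.ttest_1samp(z[:, t], 0, alternative="greater").pvalue
            assert group_p[t] == pytest.approx(expect)


def make_curve(qualify, step=20.0, start=0.0):
    """DecodingCurve whose joint selection criterion equals `qualify`."""
    qualify = np.asarray(qualify, dtype=bool)
    n = qualify.size
    acc = np.where(qualify, 0.9, 0.5)
    return DecodingCurve(
        start_times=start + step * np.arange(n),
        accuracy=np.tile(acc, (5, 1)) + np.linspace(-0.01, 0.01, 5)[:, None],
        p_within=np.full((5, n), 0.01),
        group_p=np.where(qualify, 1e-9, 0.5),
        sig_mask=qualify.copy(),
        subjects=list(range(5)),
    )


class TestSelectTimeWindow:
    def test_contiguous_window_with_short_dip_bridged(self):
        # qualifies on 80-600 ms except a 100 ms dip at 120-200; bridge=120
        starts_qualify = lambda t: (80 <= t <= 600) and not (120 <= t < 220)
        n = 36
        qual = [starts_qualify(20.0 * i) for i in range(n)]
        win = cd.select_time_window(make_curve(qual), bridge_ms=120.0)
        assert win == (80.0, 600.0)

    def test_single_timepoint_degenerate_window(self):
        qual = [False] * 5 + [True] + [False] * 5
        win = cd.select_time_window(make_curve(qual))
        assert win == (100.0, 100.0)

    def test_longer_run_wins_and_tie_goes_earlier(self):
        qual = [True, True, False] + [False] * 9 + [True, True, True]
        assert cd.select_time_window(make_curve(qual), bridge_ms=40.0) == (240.0, 280.0)
        tie = [True, True] + [False] * 10 + [True, True]
        assert cd.select_time_window(make_curve(tie), bridge_ms=40.0) == (0.0, 20.0)

    def test_no_qualifying_timepoint_returns_none(self):
        assert cd.select_time_window(make_curve([False] * 8)) is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=30), st.sampled_from([30.0, 50.0, 90.0]))
    def test_agrees_with_enumeration_oracle(self, qual, bridge):
        step = 20.0
        result = cd.select_time_window(make_curve(qual), bridge_ms=bridge)
        # oracle: merge qualifying indices into runs, bridging gaps < bridge
        idx = [i for i, q in enumerate(qual) if q]
        if not idx:
            assert result is None
            return
        runs = [[idx[0]]]
        for i in idx[1:]:
            if (i - runs[-1][-1] - 1) * step < bridge:
                runs[-1].append(i)
            else:
                runs.append([i])
        best = max(runs, key=lambda r: (r[-1] - r[0], -r[0]))
        assert result == (best[0] * step, best[-1] * step)


class TestLocalizerRecovery:
    def test_group_significant_timepoints_concentrate_in_signal_window(self):
        from conftest import small_config

        cfg = small_config(n_subjects=6, effect_size=2.5, seed=21)
        epochs, _ = cd.simulate_session1(cfg)
        feats = cd.sliding_window_features(epochs, step_ms=40.0)
        curve = cd.decode_localizer(feats, n_perm=25, seed=3)
        sig = curve.start_times[curve.sig_mask]
        assert sig.size > 0
        lo, hi = cfg.signal_window
        inside = (sig >= lo - 50.0) & (sig <= hi)  # window may start 50 ms early
        assert inside.mean() >= 0.9
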