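"""Signal conditioning, balancing, trial averaging, z-scoring and
sliding-window machinery."""

import numpy as np
import pandas as pd
import pytest

import oriens as o
from oriens.preprocessing import Window


def epochs_from(data, sfreq=1000.0, tmin=-1000.0, labels=None, label_col="orientation"):
    data = np.asarray(data, dtype=float)
    table = pd.DataFrame(
        {label_col: labels if labels is not None else np.zeros(data.shape[0])}
    )
    names = [f"E{i}" for i in range(data.shape[1])]
    return o.EpochsArray.from_arrays(data, sfreq, tmin, names, table)


class TestPreprocessEpochs:
    def test_decimation_halves_samples(self):
        rng = np.random.default_rng(0)
        e = epochs_from(rng.standard_normal((2, 3, 2500)))
        out = o.preprocess_epochs(e, (1, 80), 500.0, (-300, 0))
        assert out.n_samples == 1250
        assert out.sampling_rate == 500.0

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(1)
        e = epochs_from(rng.standard_normal((3, 2, 2500)) + 5.0)
        out = o.preprocess_epochs(e, (1, 80), 500.0, (-300, 0))
        bmask = (out.times >= -300) & (out.times <= 0)
        np.testing.assert_allclose(
            out.data[:, :, bmask].mean(axis=2), 0.0, atol=1e-10
        )

    def test_stopband_tone_attenuated_20db(self):
        """A pure 100 Hz sinusoid outside the 1-80 Hz band loses at least
        20 dB (matching the zero-phase filter's frequency-response oracle)."""
        t = np.arange(2500) / 1000.0
        tone = np.sin(2 * np.pi * 100.0 * t)
        e = epochs_from(tone[None, None, :])
        out = o.preprocess_epochs(e, (1, 80), 500.0, (-300, 0))
        mid = (out.times > -500) & (out.times < 1000)  # away from filtfilt edges
        ratio = np.sqrt(np.mean(out.data[0, 0, mid] ** 2)) / np.sqrt(0.5)
        assert ratio < 0.1

    def test_band_above_nyquist_rejected(self):
        e = epochs_from(np.zeros((1, 1, 2500)))
        with pytest.raises(ValueError, match="Nyquist"):
            o.preprocess_epochs(e, (1, 80), 150.0, (-300, 0))

    def test_non_integer_decimation_rejected(self):
        e = epochs_from(np.zeros((1, 1, 2500)))
        with pytest.raises(ValueError, match="divide"):
            o.preprocess_epochs(e, (1, 80), 300.0, (-300, 0))

    def test_baseline_outside_epoch_rejected(self):
        e = epochs_from(np.zeros((1, 1, 2500)))
        with pytest.raises(ValueError, match="baseline"):
            o.preprocess_epochs(e, (1, 80), 500.0, (-2000, 0))

    def test_commutes_with_trial_reordering(self):
        rng = np.random.default_rng(2)
        e = epochs_from(rng.standard_normal((4, 2, 2500)), labels=[1, 2, 3, 4])
        perm = [2, 0, 3, 1]
        a = o.preprocess_epochs(e.subset(perm), (1, 80), 500.0, (-300, 0))
        b = o.preprocess_epochs(e, (1, 80), 500.0, (-300, 0)).subset(perm)
        np.testing.assert_allclose(a.data, b.data)
        pd.testing.assert_frame_equal(a.trial_table, b.trial_table)


class TestSelectElectrodes:
    def test_selects_and_reorders(self):
        e = epochs_from(np.arange(2 * 4 * 5, dtype=float).reshape(2, 4, 5), sfreq=1000.0)
        out = o.select_electrodes(e, ["E2", "E0"])
        assert out.electrode_labels == ["E2", "E0"]
        np.testing.assert_array_equal(out.data[:, 0], e.data[:, 2])

    def test_full_list_is_identity(self):
        e = epochs_from(np.random.default_rng(0).standard_normal((2, 3, 4)))
        out = o.select_electrodes(e, e.electrode_labels)
        np.testing.assert_array_equal(out.data, e.data)

    def test_missing_label_named_in_error(self):
        e = epochs_from(np.zeros((1, 2, 3)))
        with pytest.raises(KeyError, match="XX"):
            o.select_electrodes(e, ["E0", "XX"])


class TestUndersampleBalance:
    def test_min_class_count_rule(self):
        labels = ["A"] * 16 + ["B"] * 15 + ["C"] * 14
        e = epochs_from(np.zeros((45, 1, 2)), labels=labels)
        out = o.undersample_balance(e, "orientation", seed=0)
        counts = out.trial_table["orientation"].value_counts()
        assert (counts == 14).all()

    def test_seeded_determinism(self):
        labels = ["A"] * 10 + ["B"] * 7
        e = epochs_from(np.random.default_rng(3).standard_normal((17, 1, 2)), labels=labels)
        a = o.undersample_balance(e, "orientation", seed=5)
        b = o.undersample_balance(e, "orientation", seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_already_balanced_keeps_all(self):
        labels = ["A"] * 5 + ["B"] * 5
        e = epochs_from(np.random.default_rng(4).standard_normal((10, 1, 2)), labels=labels)
        out = o.undersample_balance(e, "orientation", seed=1)
        assert out.n_trials == 10


class TestAverageIntoSets:
    def test_equal_group_sizes_with_remainder_dropped(self):
        labels = ["A"] * 23
        e = epochs_from(np.random.default_rng(5).standard_normal((23, 2, 3)), labels=labels)
        out = o.average_into_sets(e, 5, seed=0)
        assert out.n_trials == 5
        assert (out.trial_table["n_averaged"] == 4).all()

    def test_one_trial_per_set_is_identity(self):
        e = epochs_from(np.random.default_rng(6).standard_normal((5, 1, 3)), labels=["A"] * 5)
        out = o.average_into_sets(e, 5, seed=0)
        # Same trials, possibly reordered.
        got = np.sort(out.data, axis=0)
        np.testing.assert_allclose(got, np.sort(e.data, axis=0))

    def test_constant_trials_average_to_constant(self):
        e = epochs_from(np.full((10, 1, 3), 7.0), labels=["A"] * 10)
        out = o.average_into_sets(e, 5, seed=0)
        np.testing.assert_allclose(out.data, 7.0)

    def test_class_mean_conserved(self):
        rng = np.random.default_rng(7)
        e = epochs_from(rng.standard_normal((20, 2, 3)), labels=["A"] * 20)
        out = o.average_into_sets(e, 5, seed=1)
        np.testing.assert_allclose(out.data.mean(axis=0), e.data.mean(axis=0), atol=1e-12)

    def test_too_few_trials_rejected(self):
        e = epochs_from(np.zeros((3, 1, 2)), labels=["A"] * 3)
        with pytest.raises(ValueError, match="fewer"):
            o.average_into_sets(e, 5, seed=0)


class TestZscore:
    def test_training_statistics_define_the_transform(self):
        # Per-electrode train values {-2, 6}: mean 2, SD 4; test value 10 -> 2.
        train = epochs_from(np.array([[[-2.0, -2.0]], [[6.0, 6.0]]]), sfreq=1000.0, tmin=0.0)
        test = epochs_from(np.full((1, 1, 2), 10.0), sfreq=1000.0, tmin=0.0)
        tr, te = o.zscore_train_test(train, test, (0.0, 1.0))
        np.testing.assert_allclose(te.data, 2.0)
        assert tr.data[:, 0].mean() == pytest.approx(0.0)
        assert tr.data[:, 0].std() == pytest.approx(1.0)

    def test_test_equal_train_transforms_identically(self):
        rng = np.random.default_rng(8)
        e = epochs_from(rng.standard_normal((4, 3, 10)), sfreq=1000.0, tmin=0.0)
        tr, te = o.zscore_train_test(e, e, (0.0, 9.0))
        np.testing.assert_allclose(tr.data, te.data)

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(9)
        e = epochs_from(rng.standard_normal((6, 2, 50)), sfreq=1000.0, tmin=0.0)
        once, _ = o.zscore_train_test(e, e, (0.0, 49.0))
        twice, _ = o.zscore_train_test(once, once, (0.0, 49.0))
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_zero_variance_electrode_rejected(self):
        e = epochs_from(np.zeros((2, 1, 5)), sfreq=1000.0, tmin=0.0)
        with pytest.raises(ValueError, match="zero standard deviation"):
            o.zscore_train_test(e, e, (0.0, 4.0))


class TestSlidingWindows:
    def test_canonical_layout_has_551_windows(self):
        times = -300.0 + 2.0 * np.arange(601)  # 500 Hz over -300..900
        ws = o.sliding_windows(times, o.WindowSpec(100.0, 2.0, (-300.0, 900.0)))
        assert len(ws) == 551
        assert ws[0].sl.stop - ws[0].sl.start == 50
        assert ws[0].center_ms == -250.0
        assert ws[-1].center_ms == 850.0

    def test_width_equal_to_range_gives_one_window(self):
        times = np.arange(0.0, 100.0, 2.0)
        ws = o.sliding_windows(times, o.WindowSpec(98.0, 10.0, (0.0, 98.0)))
        assert len(ws) == 1

    def test_step_equal_to_slack_gives_two_windows(self):
        times = np.arange(0.0, 200.0, 2.0)
        ws = o.sliding_windows(times, o.WindowSpec(100.0, 98.0, (0.0, 198.0)))
        assert len(ws) == 2

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            o.WindowSpec(0.0, 2.0, (0.0, 100.0))
        with pytest.raises(ValueError):
            o.WindowSpec(100.0, 2.0, (0.0, 50.0))


class TestExtractWindowFeatures:
    def test_spatiotemporal_flattens_electrodes_by_samples(self):
        rng = np.random.default_rng(10)
        e = epochs_from(rng.standard_normal((3, 10, 100)), sfreq=500.0, tmin=0.0)
        w = o.sliding_windows(e.times, o.WindowSpec(100.0, 100.0, (0.0, 198.0)))[0]
        X = o.extract_window_features(e, w, "spatiotemporal")
        assert X.shape == (3, 500)

    def test_window_mean_is_one_feature_per_electrode(self):
        rng = np.random.default_rng(11)
        e = epochs_from(rng.standard_normal((3, 10, 100)), sfreq=500.0, tmin=0.0)
        w = o.sliding_windows(e.times, o.WindowSpec(100.0, 100.0, (0.0, 198.0)))[0]
        X = o.extract_window_features(e, w, "window_mean")
        assert X.shape == (3, 10)
        np.testing.assert_allclose(X, e.data[:, :, w.sl].mean(axis=2))

    def test_constant_trial_gives_constant_features(self):
        e = epochs_from(np.full((1, 2, 10), 3.5), sfreq=1000.0, tmin=0.0)
        w = Window(0.0, 2.0, slice(0, 5))
        for mode in ("spatiotemporal", "window_mean"):
            np.testing.assert_allclose(o.extract_window_features(e, w, mode), 3.5)

    def test_unknown_mode_rejected(self):
        e = epochs_from(np.zeros((1, 1, 4)), sfreq=1000.0, tmin=0.0)
        with pytest.raises(ValueError, match="mode"):
            o.extract_window_features(e, Window(0.0, 1.0, slice(0, 2)), "bogus")
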