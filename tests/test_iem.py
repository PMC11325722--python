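"""Inverted encoding model: estimation, inversion, alignment,
sensitivity and continuous decoding."""

import numpy as np
import pytest

import oriens as o
from oriens.iem import ALIGNED_OFFSETS, CrossDecoder


class TestEstimateWeights:
    def test_square_identity_system(self):
        rng = np.random.default_rng(0)
        C1 = rng.standard_normal((6, 6))
        np.testing.assert_allclose(o.estimate_weights(C1, C1), np.eye(6), atol=1e-10)

    def test_exact_forward_data_recovers_weights(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((10, 6))
        C1 = rng.standard_normal((6, 24))
        np.testing.assert_allclose(o.estimate_weights(W @ C1, C1), W, atol=1e-10)

    def test_matches_independent_least_squares_oracle(self):
        """Normal-equations estimate agrees with numpy's lstsq solver on
        random overdetermined systems to 1e-10."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            B1 = rng.standard_normal((10, 24))
            C1 = rng.standard_normal((6, 24))
            W_hat = o.estimate_weights(B1, C1)
            oracle = np.linalg.lstsq(C1.T, B1.T, rcond=None)[0].T
            np.testing.assert_allclose(W_hat, oracle, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        row = rng.standard_normal(24)
        C1 = np.vstack([row] * 6)
        with pytest.raises(np.linalg.LinAlgError):
            o.estimate_weights(rng.standard_normal((10, 24)), C1)


class TestInvertChannelResponses:
    def test_left_inverse_recovers_planted_responses(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((10, 6))
        C = rng.standard_normal((6, 4))
        np.testing.assert_allclose(o.invert_channel_responses(W, W @ C), C, atol=1e-10)

    def test_zero_data_gives_zero_responses(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((10, 6))
        np.testing.assert_allclose(
            o.invert_channel_responses(W, np.zeros((10, 4))), 0.0
        )

    def test_estimate_then_invert_roundtrip(self):
        """Noiseless forward data: estimate on one sample set, invert on
        another, recover the planted responses to 1e-8."""
        rng = np.random.default_rng(6)
        W = rng.standard_normal((10, 6))
        C1 = rng.standard_normal((6, 24))
        C2 = rng.standard_normal((6, 4))
        W_hat = o.estimate_weights(W @ C1, C1)
        np.testing.assert_allclose(
            o.invert_channel_responses(W_hat, W @ C2), C2, atol=1e-8
        )

    def test_rank_deficient_weights_rejected(self):
        W = np.zeros((10, 6))
        W[:, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError):
            o.invert_channel_responses(W, np.ones((10, 2)))


class TestAlignProfile:
    def test_peak_lands_at_center_position(self, basis):
        c_hat = basis.response(45.0)
        aligned = o.align_profile(c_hat, 45.0, basis)
        assert np.argmax(aligned) == ALIGNED_OFFSETS.index(0.0) == 3
        assert aligned[3] == pytest.approx(1.0)

    def test_negative_average_is_mirror_of_positive(self, basis):
        rng = np.random.default_rng(7)
        c_hat = rng.standard_normal(6)
        plus = o.align_profile(c_hat, 45.0, basis)
        minus = o.align_profile(c_hat[::-1], -45.0, basis)
        # Mirroring both the profile and the average flips the offset axis
        # (+30 <-> -30 etc.); the -90 offset channel maps onto itself.
        np.testing.assert_allclose(minus[[1, 2, 3, 4]], plus[[5, 4, 3, 2]][::-1][[3, 2, 1, 0]])

    def test_constant_profile_stays_constant(self, basis):
        aligned = o.align_profile(np.full(6, 2.5), 15.0, basis)
        np.testing.assert_allclose(aligned, 2.5)

    def test_off_grid_average_rejected(self, basis):
        with pytest.raises(ValueError):
            o.align_profile(np.arange(6.0), 30.0, basis)


class TestOrientationSensitivity:
    def test_flat_profile_has_zero_slope(self):
        assert o.orientation_sensitivity(np.full(6, 0.7)) == pytest.approx(0.0)

    def test_ideal_basis_profile_slope(self):
        """Hand OLS oracle on the folded cos^7 profile gives ~0.01126
        response units per degree."""
        p = np.array([0.0, 0.0078125, 0.36535446722156023, 1.0, 0.36535446722156023, 0.0078125])
        x = np.array([-90.0, -60.0, -60.0, -30.0, -30.0, 0.0])
        y = np.array([p[0], p[1], p[5], p[2], p[4], p[3]])
        oracle = np.polyfit(x, y, 1)[0]
        slope = o.orientation_sensitivity(p)
        assert slope == pytest.approx(oracle, abs=1e-12)
        assert slope == pytest.approx(0.01126, abs=1e-5)

    def test_negation_flips_sign(self):
        rng = np.random.default_rng(8)
        p = rng.standard_normal(6)
        assert o.orientation_sensitivity(-p) == pytest.approx(
            -o.orientation_sensitivity(p)
        )

    def test_profile_peaked_at_center_is_positive_opposite_negative(self, basis):
        ideal = o.align_profile(basis.response(45.0), 45.0, basis)
        assert o.orientation_sensitivity(ideal) > 0
        rotated = o.align_profile(basis.response(-45.0), 45.0, basis)
        assert o.orientation_sensitivity(rotated) < 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            o.orientation_sensitivity([1, 2, np.nan, 4, 5, 6])


class TestContinuousDecode:
    def test_self_prediction_decodes_exactly(self, basis):
        assert o.continuous_decode(basis.response(45.0), basis, 1) == 45.0

    def test_matches_exhaustive_grid_oracle(self, basis):
        """Independent oracle: brute-force correlation over all candidates
        with numpy.corrcoef."""
        rng = np.random.default_rng(9)
        for target in (30.0, 62.0, -12.0):
            c_hat = basis.response(target) + 0.01 * rng.standard_normal(6)
            sign = np.sign(target)
            grid = np.arange(-89.0, 91.0)
            grid = grid[np.sign(grid) == sign]
            oracle = grid[
                int(
                    np.argmax(
                        [np.corrcoef(c_hat, basis.response(g))[0, 1] for g in grid]
                    )
                )
            ]
            assert o.continuous_decode(c_hat, basis, sign) == oracle

    def test_invariant_to_affine_transform(self, basis):
        c_hat = basis.response(30.0)
        assert o.continuous_decode(10.0 * c_hat + 3.0, basis, 1) == o.continuous_decode(
            c_hat, basis, 1
        )

    def test_sign_restriction(self, basis):
        c_hat = basis.response(45.0)
        assert o.continuous_decode(c_hat, basis, -1) < 0

    def test_mirror_symmetry(self, basis):
        c_hat = basis.response(52.0)
        plus = o.continuous_decode(c_hat, basis, 1)
        minus = o.continuous_decode(c_hat[::-1], basis, -1)
        assert minus == -plus

    def test_constant_profile_rejected(self, basis):
        with pytest.raises(ValueError, match="constant"):
            o.continuous_decode(np.ones(6), basis, 1)

    def test_candidate_grid_has_180_entries(self):
        grid = o.candidate_orientations()
        assert grid.size == 180
        assert grid[0] == -89.0 and grid[-1] == 90.0


class TestCrossDecoding:
    def test_estimate_count_and_shapes(self, exp1_small, exp2a_small, coarse_windows):
        cfg = o.IEMConfig(n_repetitions=2, window=coarse_windows, seed=0)
        tc = o.cross_decode_timecourse(exp1_small, exp2a_small, cfg=cfg)
        assert tc.n_estimates == 10
        assert tc.responses.shape == (4, 4, 6)
        assert len(tc.condition_names) == 4

    def test_recovers_average_orientation_channel(self, exp1_small, exp2a_small):
        """High-SNR parameter recovery: in the ensemble window the peak
        channel is the one tuned to the set average."""
        window = o.WindowSpec(100.0, 1000.0, (500.0, 1000.0))  # single window 500-600
        cfg = o.IEMConfig(n_repetitions=5, window=window, seed=1)
        tc = o.cross_decode_timecourse(exp1_small, exp2a_small, cfg=cfg)
        registry = o.stimulus_sets_by_name()
        for ci, name in enumerate(tc.condition_names):
            peak = tc.basis.centers[int(np.argmax(tc.responses[0, ci]))]
            assert peak == registry[name].average

    def test_prestimulus_profiles_are_weak(self, exp1_small, exp2a_small):
        window = o.WindowSpec(100.0, 750.0, (-300.0, 900.0))  # centers -250, 500
        cfg = o.IEMConfig(n_repetitions=5, window=window, seed=2)
        tc = o.cross_decode_timecourse(exp1_small, exp2a_small, cfg=cfg)
        sens = o.sensitivity_timecourse(tc)
        for st in sens.slopes:
            assert sens.slopes[st][1] > sens.slopes[st][0]

    def test_seeded_runs_reproducible(self, exp1_small, exp2a_small, coarse_windows):
        cfg = o.IEMConfig(n_repetitions=2, window=coarse_windows, seed=3)
        a = o.cross_decode_timecourse(exp1_small, exp2a_small, cfg=cfg)
        b = o.cross_decode_timecourse(exp1_small, exp2a_small, cfg=cfg)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_electrode_mismatch_rejected(self, exp1_small, exp2a_small, coarse_windows):
        renamed = exp2a_small.copy()
        renamed.electrode_labels = [f"X{i}" for i in range(renamed.n_electrodes)]
        with pytest.raises(ValueError, match="electrode"):
            CrossDecoder(exp1_small, renamed, cfg=o.IEMConfig(window=coarse_windows))

    def test_mirror_pipeline_symmetry(self, small_model):
        """Negating every orientation label (a relabeling under which the
        channel basis is symmetric) exactly negates the decoded
        deviations.  Noiseless data so random trial grouping is
        irrelevant."""
        cfg0 = o.SimulationConfig(
            trials_per_orientation=5,
            trials_per_set=5,
            sampling_rate_hz=250.0,
            epoch_window_ms=(-400.0, 1000.0),
            noise_sd=0.0,
            participant_bias_sd=0.0,
            seed=12,
        )
        # Ensemble-phase windows only: the nonzero bias breaks the exact
        # mirror symmetry of the element-phase profile, whose decoded
        # orientation is otherwise a degenerate correlation tie.
        window = o.WindowSpec(100.0, 100.0, (400.0, 650.0))
        cfg = o.IEMConfig(n_repetitions=2, window=window, seed=4)
        e1 = o.simulate_exp1(cfg0, small_model)
        e2 = o.simulate_exp2a(cfg0, small_model, [4.0])
        tc = o.cross_decode_timecourse(e1, e2, cfg=cfg)

        # Mirror world: same voltages, orientation labels negated and the
        # ensemble conditions renamed to their mirror sets.
        m1 = e1.copy()
        m1.trial_table["orientation"] = -m1.trial_table["orientation"]
        m2 = e2.copy()
        mirror = {
            "Average 45° w": "Average -45° w",
            "Average -45° w": "Average 45° w",
            "Average 45° w/o": "Average -45° w/o",
            "Average -45° w/o": "Average 45° w/o",
        }
        m2.trial_table["set_name"] = m2.trial_table["set_name"].map(mirror)
        tcm = o.cross_decode_timecourse(m1, m2, cfg=cfg)

        dev = o.decoded_deviation_timecourse(tc)
        devm = o.decoded_deviation_timecourse(tcm)
        for st in ("w", "w/o"):
            d = dev[dev.set_type == st]["decoded_deviation_deg"].to_numpy()
            dm = devm[devm.set_type == st]["decoded_deviation_deg"].to_numpy()
            np.testing.assert_allclose(dm, -d, atol=1e-9)
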