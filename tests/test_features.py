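import logging

import numpy as np
import pytest
from scipy import stats as spstats

import wristahi as wa
from wristahi.features import (
    EpochFeatureMatrix,
    default_registry,
    sample_entropy,
)
from wristahi.pulse import IBISeries, RespSurrogate


def ibi_series(values, start=0.0):
    values = np.asarray(values, dtype=float)
    times = start + np.cumsum(values)
    return IBISeries(values, times, np.zeros(len(values), dtype=int))


def make_resp(breath_times, lengths, amps, duration):
    ts = np.arange(0, duration, 0.25)
    return RespSurrogate(
        ts,
        np.zeros_like(ts),
        np.ones_like(ts, dtype=bool),
        np.asarray(breath_times, float),
        np.asarray(lengths, float),
        np.asarray(amps, float),
    )


class TestHrvFeatures:
    def test_constant_ibis_zero_sdnn_unit_mean(self):
        grid = wa.make_epoch_grid(900.0)
        ibis = ibi_series(np.ones(900))
        mat = wa.compute_hrv_features(ibis, grid, default_registry())
        k = 15  # interior epoch: 300-s window fully inside
        assert mat.column("hrv_sdnn")[k] == pytest.approx(0.0, abs=1e-12)
        assert mat.column("hrv_mean_ibi")[k] == pytest.approx(1.0, abs=1e-9)
        assert mat.defined_mask[k, mat.feature_names.index("hrv_sdnn")]

    def test_low_coverage_undefined(self):
        # 100 s of accepted IBIs inside a 300-s window -> undefined
        grid = wa.make_epoch_grid(900.0)
        ibis = ibi_series(np.ones(100), start=400.0)  # covers [400, 500]
        mat = wa.compute_hrv_features(ibis, grid, default_registry())
        j = mat.feature_names.index("hrv_mean_ibi")
        assert not mat.defined_mask[15, j]  # window [300,600): 100/300 < 0.5

    def test_edge_epoch_window_outside_recording_undefined(self):
        grid = wa.make_epoch_grid(900.0)
        ibis = ibi_series(np.ones(900))
        mat = wa.compute_hrv_features(ibis, grid, default_registry())
        j = mat.feature_names.index("hrv_mean_ibi")  # 300-s window
        assert not mat.defined_mask[0, j]
        j30 = mat.feature_names.index("hrv_mean_ibi_30")  # 30-s window fits
        assert mat.defined_mask[0, j30]

    def test_spectral_peak_matches_modulation(self):
        # 0.25 Hz sinusoidal IBI modulation -> spectral peak at 0.25 Hz
        grid = wa.make_epoch_grid(900.0)
        t = np.cumsum(np.ones(900))
        values = 1.0 + 0.05 * np.sin(2 * np.pi * 0.25 * t)
        ibis = IBISeries(values, t, np.zeros(900, dtype=int))
        mat = wa.compute_hrv_features(ibis, grid, default_registry())
        peak = mat.column("hrv_peak_freq")[15]
        assert peak == pytest.approx(0.25, abs=0.02)
        # independent periodogram oracle on the uniform tachogram
        ts = np.arange(t[0], t[-1], 0.25)
        tach = np.interp(ts, t, values)
        from scipy.signal import periodogram

        freqs, psd = periodogram(tach - tach.mean(), fs=4.0)
        assert freqs[np.argmax(psd)] == pytest.approx(0.25, abs=0.02)

    def test_locality_outside_window(self):
        """Perturbing IBIs outside an epoch's window leaves its value alone."""
        grid = wa.make_epoch_grid(900.0)
        base = np.ones(900)
        pert = base.copy()
        pert[:60] = 1.3  # inside [0,60] s only; epoch 15 window is [300,600)
        reg = [s for s in default_registry() if s.name == "hrv_sdnn"]
        m1 = wa.compute_hrv_features(ibi_series(base), grid, reg)
        m2 = wa.compute_hrv_features(ibi_series(pert), grid, reg)
        assert m1.column("hrv_sdnn")[15] == m2.column("hrv_sdnn")[15]

    def test_sample_entropy_regular_vs_random(self):
        rng = np.random.default_rng(0)
        periodic = np.sin(np.arange(300) * 0.5)
        noise = rng.normal(size=300)
        assert sample_entropy(periodic) < sample_entropy(noise)


class TestRespFeatures:
    def test_two_breaths_undefined_three_defined(self):
        grid = wa.make_epoch_grid(120.0)
        reg = default_registry()
        two = make_resp([40.0, 44.0], [4.0, 4.0], [1.0, 1.0], 120.0)
        mat = wa.compute_resp_features(two, grid, reg)
        j = mat.feature_names.index("resp_len_mean")
        assert not mat.defined_mask[1, j]
        three = make_resp([34.0, 40.0, 44.0], [4.0] * 3, [1.0] * 3, 120.0)
        mat3 = wa.compute_resp_features(three, grid, reg)
        assert mat3.defined_mask[1, j]
        assert mat3.column("resp_len_mean")[1] == pytest.approx(4.0)
        assert mat3.column("resp_len_sd")[1] == pytest.approx(0.0, abs=1e-12)

    def test_event_epochs_have_lower_amplitude(self, analysed_night):
        rec, ann, truth, rf = analysed_night
        mat = rf.matrix
        j = mat.feature_names.index("resp_amp_mean")
        lab = truth.re_labels
        sleep = np.array([s.value != "W" for s in truth.hypnogram])[: mat.n_epochs]
        m = mat.defined_mask[:, j]
        ev = mat.values[lab & sleep & m, j]
        base = mat.values[~lab & sleep & m, j]
        assert ev.mean() < base.mean()


class TestActivityCounts:
    def test_gravity_only_zero_and_burst_locality(self):
        grid = wa.make_epoch_grid(300.0)
        fs = 128.0
        accel = np.zeros((int(300 * fs), 3))
        accel[:, 2] = 1.0  # constant gravity
        counts = wa.activity_counts(accel, fs, grid)
        assert np.allclose(counts, 0.0, atol=1e-8)
        rng = np.random.default_rng(1)
        burst = rng.normal(0, 0.5, size=(int(5 * fs), 3))
        a2 = accel.copy()
        i0 = int(7 * 30 * fs)
        a2[i0 : i0 + len(burst)] += burst
        c2 = wa.activity_counts(a2, fs, grid)
        assert np.argmax(c2) == 7
        assert np.all(np.delete(c2, 7) < 0.05 * c2[7])
        # monotone in burst amplitude
        a3 = accel.copy()
        a3[i0 : i0 + len(burst)] += 2 * burst
        assert wa.activity_counts(a3, fs, grid)[7] > c2[7]


class TestStageProbabilities:
    def test_rows_sum_to_one_and_uniform_fallback(self, analysed_night):
        rec, ann, truth, rf = analysed_night
        clf = wa.StageClassifier().fit([rf.matrix], [ann.hypnogram])
        probs = wa.sleep_stage_probabilities(rf.matrix, clf)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        # an all-undefined epoch gets uniform probabilities
        mat = EpochFeatureMatrix(
            rf.matrix.values.copy(), np.zeros_like(rf.matrix.defined_mask), rf.matrix.feature_names
        )
        probs0 = wa.sleep_stage_probabilities(mat, clf)
        assert np.allclose(probs0, 0.25)

    def test_wake_detection_on_held_out_night(self, analysed_night):
        rec, ann, truth, rf = analysed_night
        cfg = wa.SimConfig(duration_h=1.0, target_ahi=20.0, seed=77)
        rec2, ann2, truth2 = wa.simulate_recording(cfg, seed=77)
        rf2 = wa.extract_recording_features(rec2)
        clf = wa.StageClassifier().fit([rf.matrix], [ann.hypnogram])
        probs = wa.sleep_stage_probabilities(rf2.matrix, clf)
        wake = np.array([s.value == "W" for s in truth2.hypnogram])[: rf2.matrix.n_epochs]
        assert np.mean(probs[wake, 0] > 0.5) >= 0.9


class TestNormalization:
    def _matrix(self, cols):
        values = np.column_stack(cols)
        return EpochFeatureMatrix(
            values, np.isfinite(values), [f"f{j}" for j in range(values.shape[1])]
        )

    def test_identity_lambda_z_scores(self):
        mat = self._matrix([np.array([1.0, 2.0, 3.0])])
        params = wa.fit_normalization(mat)
        assert params.lambdas[0] == 1.0
        out = wa.apply_normalization(mat, params)
        assert np.allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_lognormal_selects_log_and_reduces_skew(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(0, 1, size=10_000))
        mat = self._matrix([x])
        params = wa.fit_normalization(mat)
        assert params.lambdas[0] == 0.0
        out = wa.apply_normalization(mat, params)
        assert abs(spstats.skew(out.values[:, 0])) < abs(spstats.skew(x))

    def test_train_matrix_through_own_params_standardised(self):
        rng = np.random.default_rng(6)
        cols = [rng.gamma(2.0, 1.0, 500), rng.normal(5, 2, 500)]
        mat = self._matrix(cols)
        mat.defined_mask[rng.random(500) < 0.2, 0] = False  # undefined entries
        params = wa.fit_normalization(mat)
        out = wa.apply_normalization(mat, params)
        for j in range(2):
            d = out.values[out.defined_mask[:, j], j]
            assert abs(d.mean()) < 1e-8
            assert abs(d.std(ddof=1) - 1.0) < 1e-8
        # undefined entries zero-filled, mask unchanged
        assert np.all(out.values[~out.defined_mask[:, 0], 0] == 0.0)

    def test_constant_feature_excluded(self):
        mat = self._matrix([np.full(50, 3.0), np.arange(50.0)])
        params = wa.fit_normalization(mat)
        assert params.excluded[0] and not params.excluded[1]
        out = wa.apply_normalization(mat, params)
        assert np.all(out.values[:, 0] == 0.0)
        assert not out.defined_mask[:, 0].any()

    def test_below_domain_clamped_with_warning(self, caplog):
        rng = np.random.default_rng(7)
        train = self._matrix([np.exp(rng.normal(0, 1, 1000))])
        params = wa.fit_normalization(train)
        assert params.lambdas[0] == 0.0
        apply = self._matrix([np.array([-1.0, 1.0, 2.0])])  # below log domain
        with caplog.at_level(logging.WARNING, logger="wristahi"):
            out = wa.apply_normalization(apply, params)
        assert np.all(np.isfinite(out.values))
        assert any("clamped" in r.message for r in caplog.records)
        # clamped to the domain edge: same output as the smallest trained value
        edge = self._matrix([np.array([params.floors[0], 1.0, 2.0])])
        assert np.allclose(out.values, wa.apply_normalization(edge, params).values)

    def test_split_safety(self):
        """Appending hold-out rows must not change the fitted parameters."""
        rng = np.random.default_rng(8)
        train = self._matrix([rng.gamma(2.0, 1.0, 400)])
        holdout = self._matrix([rng.gamma(9.0, 3.0, 400)])
        p_train = wa.fit_normalization(train)
        both = EpochFeatureMatrix(
            np.vstack([train.values, holdout.values]),
            np.vstack([train.defined_mask, holdout.defined_mask]),
            train.feature_names,
        )
        p_both = wa.fit_normalization(both)
        applied_train_only = wa.apply_normalization(holdout, p_train)
        # the hold-out never influences the params actually used
        assert p_train.means[0] != p_both.means[0]
        assert np.isfinite(applied_train_only.values).all()


class TestTruncation:
    def test_leading_and_trailing_runs_removed(self):
        counts = np.concatenate([np.full(10, 9.0), np.zeros(800), np.full(6, 9.0)])
        grid = wa.make_epoch_grid(30.0 * len(counts))
        assert wa.truncate_recording(counts, grid) == (10, 810)

    def test_no_high_counts_full_range(self):
        counts = np.zeros(100)
        grid = wa.make_epoch_grid(3000.0)
        assert wa.truncate_recording(counts, grid) == (0, 100)

    def test_interior_movement_preserved(self):
        counts = np.zeros(100)
        counts[40:50] = 9.0
        grid = wa.make_epoch_grid(3000.0)
        assert wa.truncate_recording(counts, grid) == (0, 100)

    def test_short_edge_runs_kept(self):
        counts = np.concatenate([np.full(3, 9.0), np.zeros(97)])
        grid = wa.make_epoch_grid(3000.0)
        assert wa.truncate_recording(counts, grid) == (0, 100)  # run of 3 < 4

    def test_all_high_fatal(self):
        counts = np.full(100, 9.0)
        grid = wa.make_epoch_grid(3000.0)
        with pytest.raises(ValueError, match="no rest period"):
            wa.truncate_recording(counts, grid, threshold=5.0)


class TestMatrixContracts:
    def test_coverage_consistent_with_mask(self, analysed_night):
        *_, rf = analysed_night
        mat = rf.matrix
        recomputed = 100.0 * (~mat.defined_mask).sum(axis=1) / mat.defined_mask.shape[1]
        assert np.allclose(mat.coverage_feature, recomputed)

    def test_unknown_family_fatal(self):
        with pytest.raises(ValueError, match="family"):
            wa.FeatureSpec("bogus", "wavelets", 60, "ibi")
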