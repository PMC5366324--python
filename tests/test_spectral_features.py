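"""Burg estimation, AR spectra, band amplitudes, window bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from eegnaming.session_model import DEFAULT_LAYOUT, EEGSession, ResponseCategory, TrialEvent
from eegnaming.spectral_features import (
    EpochTooShortError,
    SpectralConfig,
    ar_spectrum,
    band_amplitudes,
    build_feature_table,
    feature_labels,
    fit_ar_burg,
    reflection_coefficients,
    sliding_window_features,
    trial_features,
    window_count,
)

CFG = SpectralConfig()


def simulate_ar2(a1, a2, n, rng, burn=2000):
    return sps.lfilter([1.0], [1.0, -a1, -a2], rng.standard_normal(n + burn))[burn:]


class TestBurg:
    def test_ar2_coefficient_recovery(self, rng):
        errs = []
        for _ in range(20):
            x = simulate_ar2(1.0, -0.8, 2560, rng)
            m = fit_ar_burg(x, 2)
            errs.append(np.abs(m.coefficients - [1.0, -0.8]).max())
        assert max(errs) < 0.05

    def test_agrees_with_statsmodels_burg(self, rng):
        from statsmodels.regression.linear_model import burg as sm_burg

        x = simulate_ar2(0.5, -0.3, 1024, rng)
        mine = fit_ar_burg(x, 6)
        theirs, _ = sm_burg(x - x.mean(), 6)
        assert np.allclose(mine.coefficients, theirs, atol=1e-10)

    def test_white_noise_order_40_is_flat(self, rng):
        x = rng.standard_normal(60 * 256)
        m = fit_ar_burg(x, 40, fs=256)
        assert np.abs(m.coefficients).max() < 0.1
        ba = band_amplitudes(m, CFG)
        assert 20 * math.log10(ba.max() / ba.min()) < 3.0  # flat within 3 dB

    def test_constant_segment_degenerate(self):
        m = fit_ar_burg(np.full(300, 7.5), 40)
        assert m.degenerate and m.sigma2 == 0.0
        assert np.all(band_amplitudes(m, CFG) == 0.0)

    def test_segment_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            fit_ar_burg(np.zeros(40), 40)

    def test_reflection_coefficients_inside_unit_interval(self, rng):
        for _ in range(10):
            x = simulate_ar2(1.0, -0.8, 256, rng)
            k = reflection_coefficients(x, 40)
            assert np.all(np.abs(k) < 1.0)


class TestSpectrum:
    def test_order_zero_model_flat(self):
        from eegnaming.spectral_features import ARModel

        model = ARModel(order=0, coefficients=np.zeros(0), sigma2=1.0, fs=256)
        amps = ar_spectrum(model, np.linspace(1, 120, 50))
        assert np.allclose(amps, amps[0])

    def test_ar2_resonance_peak_location(self, rng):
        # pole angle: cos(theta) = a1 / (2 r), r = sqrt(-a2)
        a1, a2 = 1.0, -0.8
        f_peak = math.acos(a1 / (2 * math.sqrt(-a2))) / (2 * math.pi) * 256
        x = simulate_ar2(a1, a2, 60 * 256, rng)
        m = fit_ar_burg(x, 2, fs=256)
        freqs = np.linspace(1, 127, 2000)
        amps = ar_spectrum(m, freqs)
        assert abs(freqs[np.argmax(amps)] - f_peak) < 1.0

    def test_frequency_out_of_range(self):
        from eegnaming.spectral_features import ARModel

        model = ARModel(order=0, coefficients=np.zeros(0), sigma2=1.0, fs=256)
        with pytest.raises(ValueError):
            ar_spectrum(model, [130.0])

    def test_band_amplitudes_match_periodogram_oracle(self, rng):
        # 5 independent 60-s realizations; compare ensemble-mean band
        # amplitudes so estimator variance does not swamp the comparison
        theta = 2 * math.pi * 10 / 256
        r = math.exp(-math.pi * 4 / 256)
        mine, oracle = [], []
        for _ in range(5):
            x = simulate_ar2(2 * r * math.cos(theta), -r * r, 60 * 256, rng)
            x = x + 0.5 * rng.standard_normal(x.size)
            mine.append(band_amplitudes(fit_ar_burg(x, 40, fs=256), CFG))
            f, pxx = sps.welch(x, fs=256, nperseg=4096)
            amp = np.sqrt(pxx / 2)  # one-sided density -> two-sided amplitude
            oracle.append(
                [np.interp(CFG.band_grid(b), f, amp).mean() for b in CFG.bands]
            )
        mine, oracle = np.mean(mine, axis=0), np.mean(oracle, axis=0)
        assert np.all(np.abs(mine - oracle) / oracle < 0.10)

    def test_planted_10hz_rhythm_maximizes_alpha_band(self, rng):
        t = np.arange(10 * 256) / 256
        x = np.sin(2 * math.pi * 10.0 * t) + 0.1 * rng.standard_normal(t.size)
        ba = band_amplitudes(fit_ar_burg(x, 40, fs=256), CFG)
        assert np.argmax(ba) == 1  # 10-13 Hz band

    def test_amplitude_homogeneity_under_gain(self, rng):
        x = simulate_ar2(1.0, -0.8, 2048, rng)
        b1 = band_amplitudes(fit_ar_burg(x, 40, fs=256), CFG)
        b2 = band_amplitudes(fit_ar_burg(3.0 * x, 40, fs=256), CFG)
        assert np.allclose(b2, 3.0 * b1, rtol=1e-8)


class TestWindows:
    def test_ten_second_epoch_gives_145_windows(self):
        assert window_count(2560, 256, CFG) == 145

    def test_single_and_zero_window_edges(self):
        assert window_count(256, 256, CFG) == 1
        assert window_count(255, 256, CFG) == 0  # 999 ms

    @given(st.integers(min_value=256, max_value=6000))
    @settings(max_examples=200, deadline=None)
    def test_window_count_formula(self, n):
        assert window_count(n, 256, CFG) == (n - 256) // 16 + 1

    def test_window_config_must_be_integer_samples(self):
        bad = SpectralConfig(window_step_ms=60.0)  # 15.36 samples at 256 Hz
        with pytest.raises(ValueError, match="whole number"):
            bad.step_samples(256)


def _stationary_session(rng, n_sec=30):
    n = n_sec * 256
    sig = np.vstack(
        [simulate_ar2(1.0, -0.8, n, rng) * 5 + rng.standard_normal(n) for _ in range(16)]
    )
    trials = [
        TrialEvent(256, 256 + 2560, ResponseCategory.CORRECT, "x", 1),
        TrialEvent(3200, None, ResponseCategory.NO_RESPONSE, "y", 1),
    ]
    return EEGSession(
        signal=sig, fs=256, layout=DEFAULT_LAYOUT, trials=trials,
        participant_id="stat", session_index=1,
    ).validate()


class TestTrialFeatures:
    def test_sliding_windows_count_and_shape(self, rng):
        sess = _stationary_session(rng)
        wins = sliding_window_features(sess, "Cz", (256, 256 + 2560))
        assert wins.shape == (145, 6)

    def test_short_epoch_warns_and_empty(self, rng):
        sess = _stationary_session(rng)
        with pytest.warns(UserWarning, match="shorter"):
            wins = sliding_window_features(sess, "Cz", (0, 200))
        assert wins.shape == (0, 6)

    def test_single_window_trial_equals_window_amplitudes(self, rng):
        sess = _stationary_session(rng)
        trial = TrialEvent(256, 256 + 256, ResponseCategory.CORRECT, "x", 1)
        row = trial_features(sess, trial, ["Cz"], CFG)
        win = sliding_window_features(sess, "Cz", (256, 512), CFG)
        assert np.allclose(row, win[0])

    def test_no_response_trial_averages_145_windows(self, rng):
        sess = _stationary_session(rng)
        row = trial_features(sess, sess.trials[1], ["Fz"], CFG)
        wins = sliding_window_features(sess, "Fz", sess.trials[1].epoch(256), CFG)
        assert wins.shape[0] == 145
        assert np.allclose(row, wins.mean(axis=0))

    def test_trial_average_near_whole_epoch_amplitudes(self, rng):
        # stationarity: windowed average approximates one long-epoch fit
        sess = _stationary_session(rng)
        row = trial_features(sess, sess.trials[0], ["Pz"], CFG)
        whole = band_amplitudes(
            fit_ar_burg(sess.channel("Pz")[256 : 256 + 2560], 40, fs=256), CFG
        )
        assert np.all(np.abs(row - whole) / whole < 0.25)

    def test_too_short_epoch_is_excluded_error(self, rng):
        sess = _stationary_session(rng)
        trial = TrialEvent(256, 400, ResponseCategory.CORRECT, "x", 1)
        with pytest.raises(EpochTooShortError):
            trial_features(sess, trial, ["Cz"], CFG)


class TestFeatureTable:
    def test_column_counts_for_channel_sets(self, small_planted_participant):
        _, _, sessions = small_planted_participant
        t3 = build_feature_table(sessions[:1], "3")
        assert t3.features.shape[1] == 18
        t9 = build_feature_table(sessions[:1], "9")
        assert t9.features.shape[1] == 54
        assert list(t3.features.columns) == feature_labels(("Fz", "Cz", "Pz"), CFG)

    def test_rerun_is_deterministic(self, small_planted_participant):
        _, _, sessions = small_planted_participant
        a = build_feature_table(sessions[:1], "3")
        b = build_feature_table(sessions[:1], "3")
        assert a.features.equals(b.features)

    def test_exclusions_are_logged_not_silent(self, small_planted_participant):
        _, _, sessions = small_planted_participant
        table = build_feature_table(sessions, "3")
        n_trials = sum(len(s.trials) for s in sessions)
        assert table.n_trials + len(table.exclusions) == n_trials

    def test_round_trip_tsv(self, small_planted_participant, tmp_path):
        _, _, sessions = small_planted_participant
        table = build_feature_table(sessions[:1], "3")
        table.to_tsv(tmp_path / "t.tsv")
        from eegnaming.spectral_features import FeatureTable

        back = FeatureTable.from_tsv(tmp_path / "t.tsv", table.channels)
        assert np.allclose(back.features.values, table.features.values)
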