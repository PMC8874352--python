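"""Blink detector: preprocessing, candidate intervals, landmark fits,
stereotypy filters, and recovery against ground truth."""

import numpy as np
import pytest

from blinkhazard import blink_detect as B
from blinkhazard import synth_eog as S

FS = 500.0


class TestPreprocess:
    def test_drift_rejected(self):
        t = np.arange(0, 60, 1 / FS)
        drift = 50.0 * np.sin(2 * np.pi * 0.1 * t)
        out = B.preprocess(drift, FS)
        # stop-band: a 0.1-Hz oscillation carries almost no in-band energy
        raw_band = B.preprocess(
            drift + 1.0 * np.sin(2 * np.pi * 5.0 * t), FS)
        corr = np.corrcoef(out, drift)[0, 1] if out.std() > 0 else 0.0
        assert np.abs(
            np.corrcoef(raw_band, np.sin(2 * np.pi * 5.0 * t))[0, 1]) > 0.99

    def test_white_noise_standardized(self):
        rng = np.random.default_rng(0)
        out = B.preprocess(rng.standard_normal(30000), FS)
        assert abs(out.std() - 1.0) < 1e-6
        assert abs(out.mean()) < 1e-9

    def test_blink_peaks_preserved(self):
        times = np.arange(2000.0, 50000.0, 4000.0)
        rec, _ = S.render_recording(times, noise_sd=0.0, duration_ms=52000.0,
                                    rng=np.random.default_rng(1))
        raw = rec.channels["upperV"]
        z = B.preprocess(raw, FS)
        idx = np.round(times * FS / 1000.0).astype(int)
        rel_raw = raw[idx] / raw[idx].mean()
        rel_z = z[idx] / z[idx].mean()
        np.testing.assert_allclose(rel_z, rel_raw, rtol=0.05)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            B.preprocess(np.zeros(10), FS)

    def test_low_fs_raises(self):
        with pytest.raises(ValueError):
            B.preprocess(np.zeros(1000), 50.0)


class TestFindCandidates:
    def test_flat_trace_empty(self):
        assert B.find_candidates(np.zeros(1000), FS) == []

    def test_single_blink_found(self, default_recording):
        rec, log = default_recording
        z = B.preprocess(rec.channels["upperV"], FS)
        ivs = B.find_candidates(z, FS)
        first_peak = int(round(log.blink_peaks_ms[0] * FS / 1000.0))
        assert any(a <= first_peak < b for a, b in ivs)

    def test_nearby_runs_merged(self):
        z = np.zeros(5000)
        # two 60-ms supra-threshold bumps 40 ms apart
        z[1000:1030] = 10.0
        z[1050:1080] = 10.0
        ivs = B.find_candidates(z, FS)
        assert len(ivs) == 1

    def test_short_runs_dropped(self):
        z = np.zeros(5000)
        z[1000:1010] = 10.0  # 20 ms < 50 ms minimum
        assert B.find_candidates(z, FS) == []


class TestFitLandmarks:
    def test_triangular_pulse_perfect_fit(self):
        z = np.full(3000, -0.5)
        tri = np.concatenate([np.linspace(0, 5, 50),
                              np.linspace(5, 0, 100)[1:]])
        z[1000:1000 + len(tri)] += tri + 0.5
        z[1000] = -0.01  # make flanking zero crossings explicit
        z[1000 + len(tri) - 1] = -0.01
        c = B.fit_landmarks(z, (1020, 1100), FS)
        assert c.r2_up == pytest.approx(1.0, abs=1e-3)
        assert c.r2_down == pytest.approx(1.0, abs=1e-3)

    def test_half_sine_worse_than_triangle(self):
        z = np.full(3000, -0.5)
        sine = 5 * np.sin(np.linspace(0, np.pi, 150))
        z[1000:1150] += sine + 0.5
        z[999] = -0.01
        z[1150] = -0.01
        c = B.fit_landmarks(z, (1050, 1120), FS)
        assert c.r2_up < 1.0 and c.r2_down < 1.0

    def test_no_zero_crossing_rejected(self):
        z = np.ones(3000)  # never crosses zero
        assert B.fit_landmarks(z, (1400, 1500), FS) is None

    def test_ordering_invariant(self, default_recording):
        rec, _ = default_recording
        used = B.detect_channel(rec.channels["upperV"], FS)
        for c in used:
            assert c.left_zero < c.max_frame < c.right_zero


class TestBar:
    def _candidate(self, lz, rz, mx, val):
        return B.BlinkCandidate(left_zero=lz, right_zero=rz, max_frame=mx,
                                max_value=val)

    def test_boundary_bar_20_retained(self):
        z = np.full(1000, 0.25)
        z[400:501] = 5.0
        c = self._candidate(400, 500, 450, 5.0)
        kept = B.compute_bar(z, [c])
        assert c.bar == pytest.approx(20.0, rel=1e-6)
        assert kept == [c]

    def test_bar_too_large_excluded(self):
        z = np.full(1000, 0.2)
        z[400:501] = 5.0
        c = self._candidate(400, 500, 450, 5.0)
        assert B.compute_bar(z, [c]) == []
        assert c.bar == pytest.approx(25.0, rel=1e-6)

    def test_bar_too_small_excluded(self):
        z = np.full(1000, 2.5)
        z[400:501] = 5.0
        c = self._candidate(400, 500, 450, 5.0)
        assert B.compute_bar(z, [c]) == []
        assert c.bar == pytest.approx(2.0, rel=1e-6)


class TestQualityFilters:
    def _cand(self, r2u, r2d, amp=5.0, pavr=5.0):
        c = B.BlinkCandidate(left_zero=0, right_zero=100, max_frame=50,
                             max_value=amp)
        c.upstroke_fit = B.StrokeFit(1.0, 0.0, r2u)
        c.downstroke_fit = B.StrokeFit(-1.0, 0.0, r2d)
        c.pavr = pavr
        return c

    def test_tier_assignment(self):
        c = self._cand(0.96, 0.97)
        B.apply_quality_filters([c, self._cand(0.99, 0.99)])
        assert c.tier == "better"

    def test_tier_monotone_nesting(self):
        best = self._cand(0.99, 0.99)
        better = self._cand(0.96, 0.96)
        good = self._cand(0.92, 0.92)
        none_ = self._cand(0.5, 0.99)
        used = B.apply_quality_filters([best, better, good, none_])
        assert set(c.tier for c in used) == {"best", "better", "good"}
        assert none_ not in used

    def test_amplitude_outlier_excluded(self):
        cands = [self._cand(0.99, 0.99, amp=5.0 + 0.1 * i)
                 for i in range(10)]
        outlier = self._cand(0.99, 0.99, amp=50.0)
        used = B.apply_quality_filters(cands + [outlier])
        assert outlier not in used
        assert all(c in used for c in cands)

    def test_saccadic_rise_excluded_by_pavr(self):
        # a rendered saccade step has a much sharper rise than a blink
        w = S._saccade_wave(40.0, FS) * 8.0
        z = np.full(4000, -0.2)
        z[1000:1000 + len(w)] += w
        cands = B.find_candidates(z - z.mean(), FS)
        fitted = [B.fit_landmarks(z, iv, FS) for iv in cands]
        fitted = [c for c in fitted if c is not None]
        assert fitted and all(c.pavr < B.PAVR_THRESHOLD for c in fitted)

    def test_blink_pavr_above_threshold(self, default_recording):
        rec, _ = default_recording
        used = B.detect_channel(rec.channels["upperV"], FS)
        assert used and all(c.pavr >= B.PAVR_THRESHOLD for c in used)


class TestSelectBestSignal:
    def test_full_amplitude_channel_wins(self, default_recording):
        rec, _ = default_recording
        cat = B.select_best_signal(rec, participant_id="t")
        assert cat.channel == "upperV"

    def test_single_channel_input(self, default_recording):
        rec, _ = default_recording
        single = S.ContinuousRecording({"Fz": rec.channels["Fz"]}, fs=rec.fs)
        cat = B.select_best_signal(single, channels=("Fz",))
        assert cat.channel == "Fz"

    def test_few_blinks_flagged_unstable(self):
        times = np.arange(2000.0, 50000.0, 4000.0)  # 12 blinks
        rec, _ = S.render_recording(times, duration_ms=52000.0,
                                    rng=np.random.default_rng(5))
        cat = B.select_best_signal(rec)
        assert cat.unstable

    def test_no_channel_raises(self, default_recording):
        rec, _ = default_recording
        with pytest.raises(ValueError):
            B.select_best_signal(rec, channels=("Cz",))


class TestRecovery:
    def test_recovery_and_ibi_range(self, default_recording):
        rec, log = default_recording
        cat = B.select_best_signal(rec, participant_id="r")
        det = cat.peak_times_ms()
        truth = log.blink_peaks_ms
        hits = sum(1 for t in truth if np.min(np.abs(det - t)) <= 20.0)
        fps = sum(1 for d in det if np.min(np.abs(truth - d)) > 20.0)
        assert hits / len(truth) >= 0.95
        assert fps / len(truth) <= 0.05
        ibis = cat.inter_blink_intervals_ms()
        assert np.all(ibis > 0)
        assert 3000.0 <= np.median(ibis) <= 5000.0
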