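"""Measurement tests: trial attribution, epoching, smoothing, and the nine
difference-wave measures, with closed-form and brute-force oracles."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oddballerp as ob
from oddballerp import erp
from oddballerp.exceptions import (
    InsufficientDataError,
    InvariantError,
    ParameterError,
    StructuralError,
)
from oddballerp.simulate import (
    ResponseEvent,
    SessionRecording,
    StimulusEvent,
)
from conftest import gaussian_bump_wave


def _stim(onset, kind="target"):
    tone = 2000.0 if kind == "target" else 750.0
    return StimulusEvent(onset_ms=onset, kind=kind, tone_frequency_hz=tone)


class TestAverageChannels:
    def test_pointwise_mean(self):
        rec = SessionRecording("s", 250.0, np.array([1.0, 1, 1]),
                               np.array([3.0, 3, 3]), [_stim(0.0)], [])
        assert np.array_equal(ob.average_channels(rec), [2.0, 2.0, 2.0])

    def test_identical_channels_identity(self, rng):
        x = rng.normal(size=100)
        rec = SessionRecording("s", 250.0, x, x.copy(), [_stim(0.0)], [])
        assert np.allclose(ob.average_channels(rec), x)

    def test_random_pair_elementwise_oracle(self, rng):
        a, b = rng.normal(size=(2, 64))
        rec = SessionRecording("s", 250.0, a, b, [_stim(0.0)], [])
        out = ob.average_channels(rec)
        assert np.allclose(out, [(x + y) / 2 for x, y in zip(a, b)])

    def test_length_mismatch_is_structural_error(self):
        with pytest.raises((StructuralError, ValueError)):
            SessionRecording("s", 250.0, np.zeros(3), np.zeros(4), [_stim(0.0)], [])


class TestAttributeResponses:
    @pytest.mark.parametrize(
        "stimuli, presses, expected, n_stray",
        [
            # target answered at a typical latency
            ([("target", 0.0)], [348.0], ["hit"], 0),
            # unanswered target
            ([("target", 0.0)], [], ["omission"], 0),
            # standard answered -> commission; press too early -> stray
            ([("standard", 0.0)], [300.0], ["commission"], 0),
            ([("standard", 0.0)], [50.0], ["correct_rejection"], 1),
            # window boundaries are inclusive
            ([("target", 0.0)], [100.0], ["hit"], 0),
            ([("target", 0.0)], [1000.0], ["hit"], 0),
            ([("target", 0.0)], [1000.5], ["omission"], 1),
            # first press wins; the second is stray
            ([("target", 0.0)], [200.0, 400.0], ["hit"], 1),
            # press goes to the most recent eligible stimulus
            ([("standard", 0.0), ("target", 600.0)], [800.0],
             ["correct_rejection", "hit"], 0),
        ],
    )
    def test_classification_cases(self, stimuli, presses, expected, n_stray):
        stims = [_stim(t, k) for k, t in stimuli]
        resp = [ResponseEvent(t) for t in presses]
        trials, stray = ob.attribute_responses(stims, resp, (100.0, 1000.0))
        assert [t.classification for t in trials] == expected
        assert stray == n_stray

    def test_hit_latency_recorded(self):
        trials, _ = ob.attribute_responses([_stim(0.0)], [ResponseEvent(348.0)])
        assert trials[0].response_time_ms == pytest.approx(348.0)

    def test_press_boundary_enumeration(self):
        """Sweep a single press across the window; classification flips at
        exactly the window edges (brute-force oracle)."""
        stim = [_stim(1000.0, "standard")]
        for press in np.arange(1000.0, 2300.0, 37.0):
            trials, stray = ob.attribute_responses(stim, [ResponseEvent(press)])
            latency = press - 1000.0
            expected = "commission" if 100.0 <= latency <= 1000.0 else "correct_rejection"
            assert trials[0].classification == expected
            assert stray == (expected == "correct_rejection")


class TestEpoching:
    def test_index_arithmetic(self):
        signal = np.arange(2000, dtype=float)
        stim = _stim(4000.0)  # sample 1000 at 250 Hz
        trials = [erp.TrialRecord(stim, 300.0, "hit")]
        epochs = ob.extract_epochs(signal, trials, "target")
        assert epochs.shape == (1, 250)
        assert epochs[0, 0] == 950 and epochs[0, -1] == 1199
        assert epochs[0, erp.ONSET_INDEX] == 1000

    def test_only_correct_trials_of_condition(self):
        signal = np.zeros(5000)
        trials = [
            erp.TrialRecord(_stim(2000.0, "standard"), 300.0, "commission"),
            erp.TrialRecord(_stim(4000.0, "standard"), None, "correct_rejection"),
            erp.TrialRecord(_stim(6000.0, "target"), None, "omission"),
            erp.TrialRecord(_stim(8000.0, "target"), 350.0, "hit"),
        ]
        assert ob.extract_epochs(signal, trials, "standard").shape[0] == 1
        assert ob.extract_epochs(signal, trials, "target").shape[0] == 1

    def test_constant_signal_gives_constant_epochs(self):
        signal = np.full(1000, 3.25)
        trials = [erp.TrialRecord(_stim(2000.0), 300.0, "hit")]
        epochs = ob.extract_epochs(signal, trials, "target")
        assert np.all(epochs == 3.25)

    def test_out_of_bounds_trial_skipped(self):
        signal = np.zeros(100)
        trials = [erp.TrialRecord(_stim(100.0), 300.0, "hit")]  # window starts < 0
        assert ob.extract_epochs(signal, trials, "target").shape[0] == 0


class TestBaselineAndSmoothing:
    def test_constant_epoch_zeroed(self):
        assert np.allclose(ob.baseline_correct(np.full(250, 7.5)), 0.0)

    def test_baseline_mean_removed(self, rng):
        epoch = rng.normal(2.5, 1.0, size=250)
        out = ob.baseline_correct(epoch)
        assert abs(out[:50].mean()) < 1e-9
        assert np.allclose(out, epoch - epoch[:50].mean())

    def test_smooth_dc_invariance(self):
        assert np.allclose(ob.smooth_trace(np.full(100, 4.2)), 4.2)

    def test_smooth_impulse_response(self):
        x = np.zeros(51)
        x[25] = 1.0
        out = ob.smooth_trace(x, 9)
        assert np.allclose(out[21:30], 1 / 9)
        assert np.allclose(np.delete(out, range(21, 30)), 0.0)

    def test_smooth_even_taps_rejected(self):
        with pytest.raises(ParameterError):
            ob.smooth_trace(np.zeros(10), 8)

    def test_smooth_interior_equals_windowed_mean(self, rng):
        x = rng.normal(size=80)
        out = ob.smooth_trace(x, 9)
        for i in range(4, 76):
            assert out[i] == pytest.approx(x[i - 4:i + 5].mean())

    def test_average_erp_identity_symmetry_oracle(self, rng):
        e = rng.normal(size=(1, 250))
        assert np.allclose(ob.average_erp(e), e[0])
        pair = np.stack([e[0], -e[0]])
        assert np.allclose(ob.average_erp(pair), 0.0)
        k = rng.normal(size=(7, 250))
        assert np.allclose(ob.average_erp(k), k.mean(axis=0))
        with pytest.raises(InsufficientDataError):
            ob.average_erp(np.empty((0, 250)))

    def test_difference_wave_algebra(self, rng):
        t = rng.normal(size=250)
        s = rng.normal(size=250)
        assert np.allclose(ob.difference_wave(t, t), 0.0)
        assert np.allclose(ob.difference_wave(t, np.zeros(250)), t)
        assert np.allclose(ob.difference_wave(t, s), t - s)
        with pytest.raises(StructuralError):
            ob.difference_wave(t, s[:-1])


class TestPeakAndCrossings:
    def test_gaussian_peak_location(self):
        amp, lat, found = ob.locate_p300(gaussian_bump_wave(5.0, 400.0, 40.0))
        assert found and amp == pytest.approx(5.0) and lat == pytest.approx(400.0)

    def test_negative_wave_has_no_peak(self):
        _, _, found = ob.locate_p300(-gaussian_bump_wave(5.0, 400.0, 40.0))
        assert not found

    def test_sinusoid_argmax_matches_exhaustive_scan(self):
        t = erp.epoch_times()
        wave = np.sin(2 * np.pi * t / 530.0)
        amp, lat, found = ob.locate_p300(wave)
        window = (t >= 300) & (t <= 600)
        best = t[window][np.argmax(wave[window])]
        assert found and lat == best and amp == wave[t == best][0]

    def test_half_sine_crossings_on_support(self):
        t = erp.epoch_times()
        wave = np.sin(np.pi * (t - 250.0) / 300.0)  # zeros at exactly 250, 550
        amp, lat, found = ob.locate_p300(wave)
        t1, t2, valid = ob.zero_crossings(wave, lat)
        assert valid
        assert t1 == pytest.approx(250.0, abs=1e-9)
        assert t2 == pytest.approx(550.0, abs=1e-9)

    def test_linear_interpolation_of_crossing(self):
        # neighbours (296 ms, -1 µV) and (300 ms, +3 µV) cross at 297 ms
        t = erp.epoch_times()
        wave = np.full_like(t, -1.0)
        wave[t >= 300] = 3.0
        wave[t >= 604] = -1.0
        t1, t2, valid = ob.zero_crossings(wave, 400.0)
        assert valid and t1 == pytest.approx(297.0)

    def test_everywhere_positive_wave_invalid(self):
        wave = gaussian_bump_wave(5.0, 400.0, 40.0, offset=1.0)
        _, lat, _ = ob.locate_p300(wave)
        *_, valid = ob.zero_crossings(wave, lat)
        assert not valid

    def test_exact_zero_sample_taken_as_crossing(self):
        t = erp.epoch_times()
        wave = np.zeros_like(t)
        wave[(t >= 300) & (t <= 500)] = 2.0
        wave[t == 296] = 0.0
        t1, t2, valid = ob.zero_crossings(wave, 400.0)
        assert valid and t1 == 296.0 and t2 == 504.0

    def test_interpolated_crossings_are_roots(self, rng):
        """|wave(T1)| and |wave(T2)| vanish under linear interpolation."""
        t = erp.epoch_times()
        for _ in range(20):
            wave = gaussian_bump_wave(6.0, 420.0, 50.0) - 0.8 + 0.3 * rng.normal(size=t.size)
            wave = ob.smooth_trace(wave, 9)
            amp, lat, found = ob.locate_p300(wave)
            if not found:
                continue
            t1, t2, valid = ob.zero_crossings(wave, lat)
            if not valid:
                continue
            assert abs(np.interp(t1, t, wave)) < 1e-9
            assert abs(np.interp(t2, t, wave)) < 1e-9


class TestAreaFeatures:
    def _triangle(self, apex=10.0, lo=300.0, hi=500.0, peak=400.0):
        t = erp.epoch_times()
        up = (t >= lo) & (t <= peak)
        down = (t > peak) & (t <= hi)
        wave = np.zeros_like(t)
        wave[up] = apex * (t[up] - lo) / (peak - lo)
        wave[down] = apex * (hi - t[down]) / (hi - peak)
        return wave

    def test_symmetric_triangle(self):
        auc, fal = ob.area_features(self._triangle(), 300.0, 500.0)
        assert auc == pytest.approx(1000.0, abs=1e-9)
        assert fal == pytest.approx(400.0, abs=1e-9)

    def test_rectangle(self):
        t = erp.epoch_times()
        wave = np.where((t >= 300) & (t <= 500), 4.0, 0.0)
        auc, fal = ob.area_features(wave, 300.0, 500.0)
        assert auc == pytest.approx(800.0, abs=1e-9)
        assert fal == pytest.approx(400.0, abs=1e-9)

    def test_right_triangle_closed_form(self):
        # 10 µV at 300 ms declining linearly to 0 at 500 ms:
        # half of the 1000 µV·ms area accrues at 300 + 200 - 100*sqrt(2) ms
        t = erp.epoch_times()
        wave = np.where((t >= 300) & (t <= 500), 10.0 * (500.0 - t) / 200.0, 0.0)
        auc, fal = ob.area_features(wave, 300.0, 500.0)
        assert auc == pytest.approx(1000.0, abs=1e-9)
        assert fal == pytest.approx(300.0 + 200.0 - 100.0 * math.sqrt(2), abs=1e-6)

    def test_fal_bisects_area(self, rng):
        """Cumulative area on [T1, FAL] equals AUC/2 (1e-6 relative)."""
        t = erp.epoch_times()
        for _ in range(10):
            wave = ob.smooth_trace(
                gaussian_bump_wave(7.0, 410.0, 45.0) - 0.5
                + 0.2 * rng.normal(size=t.size), 9)
            amp, lat, found = ob.locate_p300(wave)
            t1, t2, valid = ob.zero_crossings(wave, lat)
            if not (found and valid):
                continue
            auc, fal = ob.area_features(wave, t1, t2)
            half, _ = ob.area_features(wave, t1, fal + 1e-12)
            assert half == pytest.approx(auc / 2, rel=1e-6)

    def test_nonpositive_area_rejected(self):
        t = erp.epoch_times()
        with pytest.raises(InvariantError):
            ob.area_features(np.full_like(t, -1.0), 300.0, 500.0)


class TestDerivedIntervals:
    def test_reference_triple_consistency(self):
        t2t1, falt1, t2fal = ob.derived_intervals(247.21, 484.75, 390.88)
        assert t2t1 == pytest.approx(237.54)
        assert falt1 == pytest.approx(143.67)
        assert t2fal == pytest.approx(93.87)

    def test_degenerate_ordering_rejected(self):
        with pytest.raises(InvariantError):
            ob.derived_intervals(400.0, 400.0, 400.0)

    @given(st.floats(200, 300), st.floats(0.5, 150), st.floats(0.5, 150))
    def test_additivity_property(self, t1, a, b):
        fal, t2 = t1 + a, t1 + a + b
        t2t1, falt1, t2fal = ob.derived_intervals(t1, t2, fal)
        assert t2t1 == pytest.approx(t2 - t1)
        assert falt1 + t2fal == pytest.approx(t2t1, abs=1e-9)


class TestFullPipeline:
    def test_noiseless_subject_recovery(self, noiseless_recording):
        f = ob.extract_erp_features(noiseless_recording)
        assert f.AMP == pytest.approx(8.0, abs=1e-9)
        assert abs(f.LAT - 400.0) <= 4.0

    def test_zero_amplitude_subject_invalid(self, oddball_sequence, noiseless_params):
        p = dataclasses.replace(noiseless_params, p300_amplitude_uv=0.0,
                                n100_amplitude_uv=0.0)
        rec = ob.synthesize_session(oddball_sequence, p, seed=1)
        f = ob.extract_erp_features(rec)
        assert not f.valid

    def test_validity_invariants_on_noisy_subjects(self, oddball_sequence, cn_params):
        """T1 < LAT < T2, T1 < FAL < T2, AUC > 0, exact additivity."""
        n_checked = 0
        for seed in range(8):
            rec = ob.synthesize_session(oddball_sequence, cn_params, seed=seed)
            f = ob.extract_erp_features(rec)
            if not f.valid:
                continue
            n_checked += 1
            assert f.T1 < f.LAT < f.T2
            assert f.T1 < f.FAL < f.T2
            assert 300 <= f.LAT <= 600
            assert f.AUC > 0
            assert f.T2T1 == pytest.approx(f.FALT1 + f.T2FAL, abs=1e-9)
            assert f.T2T1 == pytest.approx(f.T2 - f.T1, abs=1e-9)
        assert n_checked >= 5

    def test_order_of_operations_linearity(self, oddball_sequence, cn_params):
        """Difference of condition averages equals the average of per-trial
        (epoch-wise) differences at matched trial counts."""
        rec = ob.synthesize_session(oddball_sequence, cn_params, seed=21)
        signal = ob.average_channels(rec)
        trials, _ = ob.attribute_responses(rec.stimuli, rec.responses)
        tgt = ob.baseline_correct(ob.extract_epochs(signal, trials, "target"))
        std = ob.baseline_correct(ob.extract_epochs(signal, trials, "standard"))
        k = min(len(tgt), len(std))
        diff_of_avg = ob.average_erp(tgt[:k]) - ob.average_erp(std[:k])
        avg_of_diff = ob.average_erp(tgt[:k] - std[:k])
        assert np.allclose(diff_of_avg, avg_of_diff, atol=1e-10)

    def test_shift_equivariance_of_measurement(self):
        """Shifting the wave by whole samples shifts all latency measures and
        leaves AUC and T2T1 unchanged."""
        t = erp.epoch_times()
        rng = np.random.default_rng(99)
        wave = ob.smooth_trace(
            gaussian_bump_wave(8.0, 400.0, 45.0) - 0.6 + 0.2 * rng.normal(size=t.size), 9)
        base = ob.measure_difference_wave(wave)
        assert base.valid
        for k in (-6, 5):  # ±24/20 ms
            shifted = np.roll(wave, k)
            f = ob.measure_difference_wave(shifted)
            delta = k * 4.0
            assert f.valid
            assert f.LAT - base.LAT == pytest.approx(delta, abs=1e-9)
            assert f.T1 - base.T1 == pytest.approx(delta, abs=1e-6)
            assert f.T2 - base.T2 == pytest.approx(delta, abs=1e-6)
            assert f.FAL - base.FAL == pytest.approx(delta, abs=1e-6)
            assert f.AUC == pytest.approx(base.AUC, rel=1e-9)
            assert f.T2T1 == pytest.approx(base.T2T1, abs=1e-6)

    def test_insufficient_trials_reported(self, oddball_sequence, cn_params):
        p = dataclasses.replace(cn_params, hit_rate=0.0)
        rec = ob.synthesize_session(oddball_sequence, p, seed=2)
        f = ob.extract_erp_features(rec)
        assert not f.valid and f.reason == "no_correct_target_trials"
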