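"""Trace feature extraction: beats, CTD90, EADs, fibrillation, summaries."""

from __future__ import annotations

import numpy as np
import pytest

from cthazard.features import (
    Beat,
    FeatureConfig,
    compute_ctd90,
    detect_beats,
    detect_eads,
    detect_fibrillation,
    summarize_well,
)
from cthazard.plate import TraceRecording
from cthazard.simulate import TraceEvents, TransientShape, render_trace


def flat_trace(duration_s=30.0, fs=66.7, level=100.0, noise=5.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    return TraceRecording(samples=level + rng.normal(0, noise, n), sampling_rate_hz=fs)


class TestDetectBeats:
    def test_flat_noisy_trace_has_no_beats(self):
        assert detect_beats(flat_trace()) == []

    def test_noise_free_train_peak_times_match_generator(self, clean_shape):
        trace = render_trace(clean_shape, 60.0, 66.7, seed=0)
        beats = detect_beats(trace)
        truth = trace.truth["peak_times_s"]
        assert len(beats) == len(truth)
        dt = 1.0 / 66.7
        for beat, t_true in zip(beats, truth):
            assert abs(beat.peak_time_s - t_true) <= dt

    def test_ead_bump_not_double_counted(self):
        shape = TransientShape(
            amplitude=1000.0, decay_time_constant_ms=250.0, period_ms=1500.0, noise_sd=0.0
        )
        plain = render_trace(shape, 30.0, 66.7, seed=0)
        n_plain = len(detect_beats(plain))
        # bump at 40% amplitude on the decay of the beat near 10.5 s
        events = TraceEvents(ead_spikes=((11.18, 0.40),))
        bumped = render_trace(shape, 30.0, 66.7, seed=0, events=events)
        assert len(detect_beats(bumped)) == n_plain

    def test_nan_trace_rejected(self):
        t = flat_trace()
        t.samples[7] = np.nan
        with pytest.raises(ValueError, match="index 7"):
            detect_beats(t)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            detect_beats(flat_trace(duration_s=5.0))

    def test_beats_ordered_and_respect_refractory(self, clean_shape):
        trace = render_trace(clean_shape, 60.0, 66.7, seed=1)
        beats = detect_beats(trace)
        times = [b.peak_time_s for b in beats]
        assert times == sorted(times)
        assert min(np.diff(times)) >= FeatureConfig().refractory_s


class TestComputeCtd90:
    def test_linear_decay_gives_ninety_percent_point(self):
        # instant rise at t=0, linear decay reaching baseline at t=1000 ms
        fs = 1000.0
        n = 2000
        y = np.zeros(n)
        y[0] = 1000.0
        decay = np.linspace(1000.0, 0.0, 1001)
        y[0:1001] = decay
        trace = TraceRecording(samples=y, sampling_rate_hz=fs)
        beat = Beat(
            upstroke_time_s=0.0, peak_time_s=0.0, peak_value=1000.0,
            local_baseline=0.0, peak_index=0, upstroke_index=0,
        )
        assert compute_ctd90(trace, beat) == pytest.approx(900.0, abs=1.5)

    def test_unreached_decay_level_returns_none(self):
        # decay truncated at 85%: level never reached before "next upstroke"
        fs = 1000.0
        y = np.concatenate([np.linspace(1000.0, 150.0, 850), np.full(200, 150.0)])
        trace = TraceRecording(samples=y, sampling_rate_hz=fs)
        beat = Beat(0.0, 0.0, 1000.0, 0.0, 0, 0)
        assert compute_ctd90(trace, beat, next_upstroke_index=1049) is None

    def test_undefined_beats_excluded_from_median(self):
        # short period: decay never completes between beats -> medians drop them
        shape = TransientShape(
            amplitude=1000.0, decay_time_constant_ms=400.0, period_ms=700.0, noise_sd=0.0
        )
        trace = render_trace(shape, 70.0, 66.7, seed=0, phase="post30")
        base = render_trace(
            TransientShape(noise_sd=0.0), 70.0, 66.7, seed=0, phase="baseline"
        )
        out = summarize_well({"baseline": base, "post30": trace})
        assert out["post30"].n_ctd90_undefined > 0


class TestDetectEads:
    def test_clean_train_has_none(self, clean_shape):
        trace = render_trace(clean_shape, 30.0, 66.7, seed=2)
        beats = detect_beats(trace)
        assert detect_eads(trace, beats) == (False, 0)

    def test_three_bumps_counted(self):
        shape = TransientShape(
            amplitude=1000.0, decay_time_constant_ms=250.0, period_ms=1500.0, noise_sd=0.0
        )
        # bumps during the decay phase of three different beats
        events = TraceEvents(ead_spikes=((6.68, 0.40), (11.18, 0.40), (15.68, 0.35)))
        trace = render_trace(shape, 30.0, 66.7, seed=0, events=events)
        beats = detect_beats(trace)
        flag, count = detect_eads(trace, beats)
        assert flag and count == 3

    def test_small_bump_below_threshold_ignored(self):
        shape = TransientShape(
            amplitude=1000.0, decay_time_constant_ms=250.0, period_ms=1500.0, noise_sd=0.0
        )
        events = TraceEvents(ead_spikes=((11.18, 0.05),))
        trace = render_trace(shape, 30.0, 66.7, seed=0, events=events)
        beats = detect_beats(trace)
        assert detect_eads(trace, beats) == (False, 0)


class TestDetectFibrillation:
    def _baseline_summary(self, shape, fs=66.7):
        trace = render_trace(shape, 65.0, fs, seed=0, phase="baseline")
        base = render_trace(shape, 65.0, fs, seed=1, phase="baseline")
        return summarize_well({"baseline": base, "post30": trace})["baseline"]

    def test_normal_trace_is_not_fibrillation(self):
        shape = TransientShape(noise_sd=5.0)
        base = self._baseline_summary(shape)
        trace = render_trace(shape, 65.0, 66.7, seed=3)
        assert not detect_fibrillation(trace, base)

    def test_fast_small_transient_segment_detected(self):
        shape = TransientShape(noise_sd=5.0)
        base = self._baseline_summary(shape)
        events = TraceEvents(fibrillation=(35.0, 3.5, 0.20))  # 30-s tail
        trace = render_trace(shape, 65.0, 66.7, seed=3, events=events)
        assert detect_fibrillation(trace, base)

    def test_flat_trace_is_arrest_not_fibrillation(self):
        shape = TransientShape(noise_sd=5.0)
        base = self._baseline_summary(shape)
        assert not detect_fibrillation(flat_trace(duration_s=65.0), base)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_fibrillation(flat_trace(duration_s=65.0), None)


class TestSummarizeWell:
    fs = 66.7

    def _train(self, period_ms, duration=65.0, seed=0, phase=None, events=None):
        shape = TransientShape(period_ms=period_ms, noise_sd=4.0)
        return render_trace(shape, duration, self.fs, seed=seed, phase=phase, events=events)

    def test_four_beats_in_window_is_beat_stop(self):
        base = self._train(1000.0, phase="baseline")
        post = self._train(15000.0, phase="post30")  # 4 beats in the final minute
        out = summarize_well({"baseline": base, "post30": post})
        assert out["post30"].n_beats == 4
        assert out["post30"].beat_stop

    def test_exactly_five_beats_is_not_beat_stop(self):
        base = self._train(1000.0, phase="baseline")
        post = self._train(12000.0, phase="post30")  # 5 beats in the final minute
        out = summarize_well({"baseline": base, "post30": post})
        assert out["post30"].n_beats == 5
        assert not out["post30"].beat_stop

    def test_recovery_by_thirty_minutes_is_not_beat_stop(self):
        base = self._train(1000.0, phase="baseline")
        silent15 = flat_trace(duration_s=65.0, seed=4)
        silent15.phase = "post15"
        post30 = self._train(1000.0, seed=5, phase="post30")
        out = summarize_well({"baseline": base, "post15": silent15, "post30": post30})
        assert not out["post30"].beat_stop
        assert out["post30"].n_beats > 50

    def test_event_flags_or_over_post_phases(self):
        base = self._train(1500.0, phase="baseline")
        events = TraceEvents(ead_spikes=((11.08, 0.40),))
        shape = TransientShape(period_ms=1500.0, noise_sd=4.0)
        post15 = render_trace(shape, 65.0, self.fs, seed=6, phase="post15", events=events)
        post30 = render_trace(shape, 65.0, self.fs, seed=7, phase="post30")
        out = summarize_well({"baseline": base, "post15": post15, "post30": post30})
        assert out["post15"].ead_detected
        assert out["post30"].ead_detected  # OR-ed into the 30-min summary

    def test_missing_phase_error_names_it(self):
        base = self._train(1000.0, phase="baseline")
        with pytest.raises(ValueError, match="post30"):
            summarize_well({"baseline": base})

    def test_median_robust_to_one_outlier_beat(self):
        # one aberrant long transient in a >= 7-beat window barely moves the median
        shape = TransientShape(period_ms=1500.0, noise_sd=0.0)
        base = render_trace(shape, 65.0, self.fs, seed=0, phase="baseline")
        clean = render_trace(shape, 65.0, self.fs, seed=0, phase="post30")
        out_clean = summarize_well({"baseline": base, "post30": clean})

        events = TraceEvents(ead_spikes=((33.08, 0.40),))  # distorts one beat's decay
        bumped = render_trace(shape, 65.0, self.fs, seed=0, phase="post30", events=events)
        out_bumped = summarize_well({"baseline": base, "post30": bumped})
        assert out_bumped["post30"].ctd90_median_ms == pytest.approx(
            out_clean["post30"].ctd90_median_ms, rel=0.02
        )
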