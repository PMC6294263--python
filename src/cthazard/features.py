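"""Beat detection and per-well beating parameters from raw traces.

The whole-well fluorescence trace of a beating monolayer is reduced to
beat-level quantities — transient duration at 90% decay (CTD90), beat rate
(BR, transients per minute) and amplitude (peak minus local baseline) — and
to abnormal-phenotype flags: beating arrest, EAD-like secondary calcium
spikes during a transient's decay, and fibrillation-like sustained fast
low-amplitude activity.  Parameter summaries are medians over all beats in
a one-minute analysis window (the final minute of each recording).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .plate import TraceRecording

__all__ = [
    "FeatureConfig",
    "Beat",
    "WellSummary",
    "detect_beats",
    "compute_ctd90",
    "detect_eads",
    "detect_fibrillation",
    "summarize_well",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable thresholds of the trace-analysis stage.

    window_s: analysis window, the final stretch of each recording over
        which beat medians and the beat count are taken.
    refractory_s: minimum spacing between primary beat peaks.
    min_prominence_frac: primary-peak prominence threshold as a fraction of
        the trace's robust amplitude (2.5–97.5 percentile range).
    noise_mult: absolute prominence floor in units of the estimated sample
        noise, so flat noisy traces yield no beats.
    rise_frac: level (fraction of beat amplitude above local baseline) whose
        upward crossing defines the upstroke reference time.
    decay_frac: remaining fraction of amplitude that defines the CTD90
        endpoint (0.1 → duration at 90% of decay).
    ead_prominence_frac: prominence threshold for secondary (EAD-like)
        spikes, as a fraction of the parent beat's amplitude.
    fib_rate_ratio / fib_amp_ratio / fib_min_duration_s: a fibrillation-like
        state is a sustained (>= fib_min_duration_s) stretch whose local rate
        is >= fib_rate_ratio x baseline while local amplitude is
        <= fib_amp_ratio x baseline.
    beat_stop_br: beat rate (beats/min) below which the 30-min recording is
        scored as beating arrest (strict inequality).
    """

    window_s: float = 60.0
    refractory_s: float = 0.30
    min_prominence_frac: float = 0.55
    noise_mult: float = 10.0
    rise_frac: float = 0.10
    decay_frac: float = 0.10
    ead_prominence_frac: float = 0.15
    fib_rate_ratio: float = 3.0
    fib_amp_ratio: float = 0.3
    fib_min_duration_s: float = 20.0
    fib_window_s: float = 5.0
    beat_stop_br: float = 5.0
    min_trace_s: float = 10.0


@dataclass
class Beat:
    """One detected calcium transient."""

    upstroke_time_s: float
    peak_time_s: float
    peak_value: float
    local_baseline: float
    peak_index: int
    upstroke_index: int
    ctd90_ms: float | None = None

    @property
    def amplitude(self) -> float:
        return self.peak_value - self.local_baseline


@dataclass
class WellSummary:
    """Per-well, per-phase beating parameters and phenotype flags."""

    phase: str
    n_beats: int
    beat_rate: float  # beats per minute in the analysis window
    ctd90_median_ms: float | None
    amplitude_median: float | None
    beat_stop: bool = False
    ead_detected: bool = False
    ead_count: int = 0
    fibrillation_detected: bool = False
    n_ctd90_undefined: int = 0


def _validate_trace(trace: TraceRecording, config: FeatureConfig) -> np.ndarray:
    y = np.asarray(trace.samples, dtype=float)
    if y.size == 0:
        raise ValueError("empty trace")
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise ValueError(f"trace contains a non-finite sample at index {bad}")
    if trace.duration_s < config.min_trace_s:
        raise ValueError(
            f"trace too short ({trace.duration_s:.1f} s < {config.min_trace_s:.0f} s)"
        )
    return y


def _noise_sd(y: np.ndarray) -> float:
    """Robust noise estimate from first differences (MAD-scaled)."""
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def detect_beats(trace: TraceRecording, config: FeatureConfig | None = None) -> list[Beat]:
    """Locate primary beat peaks and their upstroke references.

    Peaks are local maxima whose prominence exceeds both a fraction of the
    trace's robust amplitude and a multiple of the sample noise, separated
    by at least the refractory period.  Secondary EAD-like spikes (smaller
    prominence) are deliberately not counted as beats.
    """
    config = config or FeatureConfig()
    y = _validate_trace(trace, config)
    fs = trace.sampling_rate_hz

    lo, hi = np.percentile(y, [2.5, 97.5])
    robust_range = float(hi - lo)
    sigma = _noise_sd(y)
    threshold = max(config.min_prominence_frac * robust_range, config.noise_mult * sigma)
    if threshold <= 0:
        return []
    distance = max(int(round(config.refractory_s * fs)), 1)
    peaks, _ = find_peaks(y, prominence=threshold, distance=distance)

    beats: list[Beat] = []
    prev = 0
    for ip in peaks:
        seg_start = prev
        base = float(np.min(y[seg_start : ip + 1]))
        amp = float(y[ip]) - base
        if amp <= 0:
            prev = ip
            continue
        level = base + config.rise_frac * amp
        iu = ip
        while iu > seg_start and y[iu - 1] > level:
            iu -= 1
        # linear interpolation of the upward level crossing
        if iu > 0 and y[iu - 1] <= level < y[iu]:
            fr = (level - y[iu - 1]) / (y[iu] - y[iu - 1])
            t_up = (iu - 1 + fr) / fs
        else:
            t_up = iu / fs
        beats.append(
            Beat(
                upstroke_time_s=float(t_up),
                peak_time_s=ip / fs,
                peak_value=float(y[ip]),
                local_baseline=base,
                peak_index=int(ip),
                upstroke_index=int(iu),
            )
        )
        prev = int(ip)

    # a final beat whose decay is cut off by the end of the recording has
    # truncated prominence; accept it from its (fully recorded) upstroke
    tail_start = (beats[-1].peak_index + distance) if beats else 0
    tail = y[tail_start:]
    if tail.size >= 3:
        ip = tail_start + int(np.argmax(tail))
        if 0 < ip < y.size - 1 and not any(b.peak_index == ip for b in beats):
            base = float(np.min(y[tail_start : ip + 1]))
            if float(y[ip]) - base >= threshold:
                level = base + config.rise_frac * (float(y[ip]) - base)
                iu = ip
                while iu > tail_start and y[iu - 1] > level:
                    iu -= 1
                if iu > 0 and y[iu - 1] <= level < y[iu]:
                    fr = (level - y[iu - 1]) / (y[iu] - y[iu - 1])
                    t_up = (iu - 1 + fr) / fs
                else:
                    t_up = iu / fs
                beats.append(
                    Beat(
                        upstroke_time_s=float(t_up),
                        peak_time_s=ip / fs,
                        peak_value=float(y[ip]),
                        local_baseline=base,
                        peak_index=int(ip),
                        upstroke_index=int(iu),
                    )
                )
    return beats


def compute_ctd90(
    trace: TraceRecording,
    beat: Beat,
    config: FeatureConfig | None = None,
    next_upstroke_index: int | None = None,
) -> float | None:
    """Transient duration (ms) from the upstroke reference to 90% decay.

    The endpoint is the first post-peak crossing of
    ``local_baseline + decay_frac * amplitude``, linearly interpolated
    between samples.  Returns None when the decay never reaches that level
    before the next beat's upstroke (the beat is excluded from medians).
    """
    config = config or FeatureConfig()
    y = np.asarray(trace.samples, dtype=float)
    fs = trace.sampling_rate_hz
    level = beat.local_baseline + config.decay_frac * beat.amplitude
    stop = next_upstroke_index if next_upstroke_index is not None else y.size
    seg = y[beat.peak_index : stop]
    below = np.flatnonzero(seg <= level)
    if below.size == 0:
        return None
    j = int(below[0])
    if j == 0:
        return None  # peak already at level: degenerate
    i1 = beat.peak_index + j
    y0, y1 = y[i1 - 1], y[i1]
    fr = (y0 - level) / (y0 - y1) if y0 != y1 else 0.0
    t_cross = (i1 - 1 + fr) / fs
    return (t_cross - beat.upstroke_time_s) * 1000.0


def detect_eads(
    trace: TraceRecording,
    beats: Sequence[Beat],
    config: FeatureConfig | None = None,
) -> tuple[bool, int]:
    """Count EAD-like secondary spikes between beat peaks.

    A secondary spike is a local maximum between a beat's peak and the next
    beat's upstroke whose prominence exceeds ``ead_prominence_frac`` of that
    beat's amplitude and that occurs before the beat's decay completes
    (before the signal first returns to the rise-threshold level).
    """
    config = config or FeatureConfig()
    y = _validate_trace(trace, config)
    count = 0
    for i, beat in enumerate(beats):
        stop = beats[i + 1].upstroke_index if i + 1 < len(beats) else y.size
        seg = y[beat.peak_index : stop]
        if seg.size < 3:
            continue
        # decay completion: first return to the 10%-amplitude level
        level = beat.local_baseline + config.decay_frac * beat.amplitude
        below = np.flatnonzero(seg <= level)
        limit = int(below[0]) if below.size else seg.size
        if limit < 3:
            continue
        prom = config.ead_prominence_frac * beat.amplitude
        sub_peaks, _ = find_peaks(seg[:limit], prominence=prom)
        sub_peaks = sub_peaks[sub_peaks > 0]
        count += int(sub_peaks.size)
    return count >= 1, count


def detect_fibrillation(
    trace: TraceRecording,
    baseline_summary: WellSummary | None,
    config: FeatureConfig | None = None,
) -> bool:
    """Detect sustained fast, low-amplitude (fibrillation-like) activity.

    Scans fixed-length windows; a window is fibrillation-like when its local
    beat rate is at least ``fib_rate_ratio`` times the well's baseline rate
    while its transient amplitude is at most ``fib_amp_ratio`` times the
    baseline amplitude.  Returns True when at least ``fib_min_duration_s``
    of consecutive windows qualify.  A flat (arrested) trace has no peaks
    and is never fibrillation.
    """
    config = config or FeatureConfig()
    if baseline_summary is None:
        raise ValueError("fibrillation detection requires the well's baseline summary")
    y = _validate_trace(trace, config)
    fs = trace.sampling_rate_hz
    base_br = baseline_summary.beat_rate
    base_amp = baseline_summary.amplitude_median
    if base_br is None or base_br <= 0 or base_amp is None or base_amp <= 0:
        return False

    sigma = _noise_sd(y)
    prom = max(0.05 * base_amp, config.noise_mult * sigma)
    win = int(round(config.fib_window_s * fs))
    if win < 4:
        return False
    needed = int(math.ceil(config.fib_min_duration_s / config.fib_window_s))
    run = 0
    for start in range(0, y.size - win + 1, win):
        seg = y[start : start + win]
        peaks, _ = find_peaks(seg, prominence=prom, distance=max(int(0.08 * fs), 1))
        rate = peaks.size * 60.0 / config.fib_window_s
        if peaks.size >= 3:
            local_amp = float(np.median(seg[peaks]) - np.min(seg))
        else:
            local_amp = math.inf
        if rate >= config.fib_rate_ratio * base_br and local_amp <= config.fib_amp_ratio * base_amp:
            run += 1
            if run >= needed:
                return True
        else:
            run = 0
    return False


def _window_beats(beats: Sequence[Beat], trace: TraceRecording, config: FeatureConfig) -> list[Beat]:
    t_end = (trace.n_samples - 1) / trace.sampling_rate_hz
    t_start = max(t_end - config.window_s, 0.0)
    return [b for b in beats if b.peak_time_s >= t_start]


def _summarize_phase(
    trace: TraceRecording,
    phase: str,
    config: FeatureConfig,
    baseline_summary: WellSummary | None = None,
) -> WellSummary:
    beats = detect_beats(trace, config)
    # attach CTD90 per beat (bounded by the next beat's upstroke)
    for i, b in enumerate(beats):
        nxt = beats[i + 1].upstroke_index if i + 1 < len(beats) else None
        b.ctd90_ms = compute_ctd90(trace, b, config, next_upstroke_index=nxt)

    in_window = _window_beats(beats, trace, config)
    ctd_vals = [b.ctd90_ms for b in in_window if b.ctd90_ms is not None]
    amp_vals = [b.amplitude for b in in_window]
    summary = WellSummary(
        phase=phase,
        n_beats=len(in_window),
        beat_rate=len(in_window) * 60.0 / min(config.window_s, trace.duration_s),
        ctd90_median_ms=float(np.median(ctd_vals)) if ctd_vals else None,
        amplitude_median=float(np.median(amp_vals)) if amp_vals else None,
        n_ctd90_undefined=len(in_window) - len(ctd_vals),
    )
    if phase in ("post15", "post30"):
        flag, n_ead = detect_eads(trace, beats, config)
        summary.ead_detected = flag
        summary.ead_count = n_ead
        if baseline_summary is not None:
            summary.fibrillation_detected = detect_fibrillation(trace, baseline_summary, config)
    if phase == "post30":
        summary.beat_stop = summary.beat_rate < config.beat_stop_br
    return summary


def summarize_well(
    traces: Mapping[str, TraceRecording],
    config: FeatureConfig | None = None,
) -> dict[str, WellSummary]:
    """Summarize one well's phases into beating parameters and flags.

    Requires the baseline and 30-min phases; the 15-min phase is optional
    and contributes only EAD/fibrillation observations.  Beating arrest is
    judged solely on the 30-min recording (a well silent at 15 min that has
    recovered by 30 min is not arrest).  The EAD and fibrillation flags on
    the returned post30 summary are the OR over both post phases.
    """
    config = config or FeatureConfig()
    for required in ("baseline", "post30"):
        if required not in traces:
            raise ValueError(f"missing required phase: {required}")

    out: dict[str, WellSummary] = {}
    out["baseline"] = _summarize_phase(traces["baseline"], "baseline", config)
    if "post15" in traces:
        out["post15"] = _summarize_phase(traces["post15"], "post15", config, out["baseline"])
    out["post30"] = _summarize_phase(traces["post30"], "post30", config, out["baseline"])
    if "post15" in out:
        out["post30"].ead_detected = out["post30"].ead_detected or out["post15"].ead_detected
        out["post30"].ead_count = max(out["post30"].ead_count, out["post15"].ead_count)
        out["post30"].fibrillation_detected = (
            out["post30"].fibrillation_detected or out["post15"].fibrillation_detected
        )
    return out
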