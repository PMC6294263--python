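"""Seeded simulator of calcium-transient plate datasets.

Emulates whole-well fluorescence recordings of spontaneously beating
hiPSC-derived cardiomyocyte monolayers on a kinetic plate reader: periodic
calcium transients with a fast (logistic) upstroke and exponential decay,
additive Gaussian noise, well-to-well heterogeneity in beat rate and
transient duration, small vehicle drift between baseline and post-compound
recordings, and concentration-dependent drug effects including EAD-like
secondary spikes, fibrillation-like fast low-amplitude activity, and
beating arrest.

Every stochastic choice derives from a master seed through a per-well
``numpy.random.SeedSequence`` spawn keyed by sorted well id, so a dataset is
fully reproducible regardless of well iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .plate import PHASES, PlateDataset, TraceRecording, Treatment

__all__ = [
    "TransientShape",
    "EffectCurve",
    "ProbCurve",
    "DrugEffectModel",
    "EventFlags",
    "TraceEvents",
    "BaselineDistributions",
    "PlateSimConfig",
    "generate_trace",
    "render_trace",
    "apply_drug_model",
    "generate_plate",
    "vehicle_layout",
    "control_plate_layout",
]

LN10 = math.log(10.0)
# Logistic upstroke spans 8 time constants, rescaled to [0, 1]; these
# constants give the closed-form time from the 10%-amplitude rise crossing
# to the kernel peak (see TransientShape.implied_ctd90_ms).
_SIG_LO = 1.0 / (1.0 + math.exp(4.0))
_SIG_HI = 1.0 / (1.0 + math.exp(-4.0))
_Q10 = _SIG_LO + 0.1 * (_SIG_HI - _SIG_LO)
RISE_TO_PEAK_TAU = 8.0 - (4.0 + math.log(_Q10 / (1.0 - _Q10)))  # ≈ 6.0466


@dataclass(frozen=True)
class TransientShape:
    """Waveform parameters of one well's periodic calcium transient.

    Units: fluorescence in arbitrary units (a.u.), time constants and the
    beat period in milliseconds.
    """

    baseline_level: float = 100.0
    amplitude: float = 1000.0
    upstroke_time_constant_ms: float = 10.0
    decay_time_constant_ms: float = 180.0
    period_ms: float = 1000.0
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.period_ms <= 0:
            raise ValueError("period must be positive")
        if self.decay_time_constant_ms <= 0 or self.upstroke_time_constant_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def rise_duration_ms(self) -> float:
        """Full duration of the logistic upstroke (kernel start to peak)."""
        return 8.0 * self.upstroke_time_constant_ms

    @property
    def implied_beat_rate(self) -> float:
        """Beats per minute implied by the period."""
        return 60000.0 / self.period_ms

    @property
    def implied_ctd90_ms(self) -> float:
        """Closed-form transient duration at 90% decay for an isolated kernel.

        Measured from the 10%-amplitude rise crossing to the 90%-decay point:
        RISE_TO_PEAK_TAU · τ_up + τ_decay · ln 10.  For overlapping transients
        (short periods) the operational value on the periodic waveform is
        slightly larger because the decay rides on the previous tail.
        """
        return RISE_TO_PEAK_TAU * self.upstroke_time_constant_ms + (
            self.decay_time_constant_ms * LN10
        )

    @staticmethod
    def from_ctd90(
        ctd90_ms: float,
        beat_rate: float,
        amplitude: float = 1000.0,
        baseline_level: float = 100.0,
        upstroke_time_constant_ms: float = 10.0,
        noise_sd: float = 8.0,
    ) -> "TransientShape":
        """Build a shape whose isolated-kernel CTD90 and beat rate are given."""
        tau_d = (ctd90_ms - RISE_TO_PEAK_TAU * upstroke_time_constant_ms) / LN10
        if tau_d <= 0:
            raise ValueError("ctd90 too short for the requested upstroke time constant")
        return TransientShape(
            baseline_level=baseline_level,
            amplitude=amplitude,
            upstroke_time_constant_ms=upstroke_time_constant_ms,
            decay_time_constant_ms=tau_d,
            period_ms=60000.0 / beat_rate,
            noise_sd=noise_sd,
        )


def _kernel(s: np.ndarray, tau_up_s: float, tau_d_s: float) -> np.ndarray:
    """Unit-amplitude transient kernel at time s (seconds) past kernel onset."""
    rise = 8.0 * tau_up_s
    out = np.zeros_like(s)
    rising = (s >= 0) & (s < rise)
    if np.any(rising):
        sig = 1.0 / (1.0 + np.exp(-(s[rising] - 4.0 * tau_up_s) / tau_up_s))
        out[rising] = (sig - _SIG_LO) / (_SIG_HI - _SIG_LO)
    decaying = s >= rise
    if np.any(decaying):
        out[decaying] = np.exp(-(s[decaying] - rise) / tau_d_s)
    return out


@dataclass(frozen=True)
class TraceEvents:
    """Abnormal-phenotype events to render into a trace.

    ead_spikes: (time_s, amplitude_fraction) of secondary spikes.
    fibrillation: (start_s, rate_multiplier, amplitude_fraction) segment that
        replaces normal beating from start_s to the end of the trace.
    arrest_after_s: beats with onset at or after this time are dropped.
    """

    ead_spikes: tuple[tuple[float, float], ...] = ()
    fibrillation: tuple[float, float, float] | None = None
    arrest_after_s: float | None = None


@dataclass(frozen=True)
class EventFlags:
    ead: bool = False
    fibrillation: bool = False
    arrest: bool = False

    def any(self) -> bool:
        return self.ead or self.fibrillation or self.arrest


def render_trace(
    shape: TransientShape,
    duration_s: float,
    sampling_rate_hz: float,
    seed: int | np.random.SeedSequence | None = 0,
    events: TraceEvents | None = None,
    first_beat_time_s: float = 0.3,
    phase: str | None = None,
) -> TraceRecording:
    """Render a trace of any duration (no minimum-length check).

    Returns a recording whose ``truth`` dict records kernel onset times,
    continuous peak times, and the events rendered — generator ground truth
    for tests, never consumed by the analysis modules.
    """
    if duration_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    events = events or TraceEvents()
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    rng = np.random.default_rng(seed)

    period_s = shape.period_ms / 1000.0
    tau_up_s = shape.upstroke_time_constant_ms / 1000.0
    tau_d_s = shape.decay_time_constant_ms / 1000.0
    rise_s = shape.rise_duration_ms / 1000.0

    onsets = np.arange(first_beat_time_s, duration_s, period_s)
    if events.arrest_after_s is not None:
        onsets = onsets[onsets < events.arrest_after_s]

    fib_beats: list[tuple[float, float, float, float]] = []  # onset, amp, tau_up, tau_d
    if events.fibrillation is not None:
        fib_start, rate_mult, amp_frac = events.fibrillation
        onsets = onsets[onsets < fib_start]
        fib_period = period_s / rate_mult
        fib_amp = shape.amplitude * amp_frac
        # fast small transients: duration scaled to fit the shortened cycle
        fib_ctd90_ms = 0.45 * fib_period * 1000.0
        fib_tau_up = min(tau_up_s, 0.08 * fib_period)
        fib_tau_d = max(
            (fib_ctd90_ms - RISE_TO_PEAK_TAU * fib_tau_up * 1000.0) / LN10, 5.0
        ) / 1000.0
        for onset in np.arange(fib_start, duration_s, fib_period):
            fib_beats.append((onset, fib_amp, fib_tau_up, fib_tau_d))

    y = np.full(n, shape.baseline_level, dtype=float)
    beats = [(float(o), shape.amplitude, tau_up_s, tau_d_s) for o in onsets]
    beats += fib_beats
    for onset, amp, k_up, k_d in beats:
        end = onset + 8.0 * k_up + 10.0 * k_d
        i0 = max(0, int(math.floor(onset * sampling_rate_hz)))
        i1 = min(n, int(math.ceil(end * sampling_rate_hz)) + 1)
        if i0 >= i1:
            continue
        y[i0:i1] += amp * _kernel(t[i0:i1] - onset, k_up, k_d)

    for spike_t, frac in events.ead_spikes:
        amp = frac * shape.amplitude
        k_up, k_d = 0.004, 0.040  # brisk secondary spike
        end = spike_t + 8.0 * k_up + 10.0 * k_d
        i0 = max(0, int(math.floor(spike_t * sampling_rate_hz)))
        i1 = min(n, int(math.ceil(end * sampling_rate_hz)) + 1)
        if i0 < i1:
            y[i0:i1] += amp * _kernel(t[i0:i1] - spike_t, k_up, k_d)

    if shape.noise_sd > 0:
        y = y + rng.normal(0.0, shape.noise_sd, n)

    truth = {
        "onset_times_s": np.array([b[0] for b in sorted(beats)]),
        "peak_times_s": np.array(sorted(b[0] + 8.0 * b[2] for b in beats)),
        "shape": shape,
        "events": events,
        "first_beat_time_s": first_beat_time_s,
    }
    return TraceRecording(samples=y, sampling_rate_hz=sampling_rate_hz, phase=phase, truth=truth)


def generate_trace(
    shape: TransientShape,
    duration_s: float,
    sampling_rate_hz: float,
    seed: int | np.random.SeedSequence | None = 0,
    events: TraceEvents | None = None,
    first_beat_time_s: float = 0.3,
    phase: str | None = None,
) -> TraceRecording:
    """Render one recording phase; requires room for the 1-min analysis window."""
    if duration_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if duration_s < 60.0:
        raise ValueError("duration must be at least 60 s so a 1-min window fits")
    return render_trace(
        shape, duration_s, sampling_rate_hz, seed, events, first_beat_time_s, phase
    )


@dataclass(frozen=True)
class EffectCurve:
    """Saturating concentration-effect curve for one beating parameter.

    Fractional change at concentration c (μM): emax · c / (c + ec50).
    Monotone in c; zero at c = 0.
    """

    emax: float
    ec50_um: float

    def __post_init__(self) -> None:
        if self.ec50_um <= 0:
            raise ValueError("ec50 must be positive")

    def effect(self, concentration_um: float) -> float:
        c = float(concentration_um)
        if c < 0:
            raise ValueError("concentration must be non-negative")
        return self.emax * c / (c + self.ec50_um)


@dataclass(frozen=True)
class ProbCurve:
    """Saturating concentration-probability curve for an event phenotype."""

    pmax: float
    ec50_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pmax <= 1.0:
            raise ValueError("pmax must lie in [0, 1]")
        if self.ec50_um < 0:
            raise ValueError("ec50 must be non-negative")

    def prob(self, concentration_um: float) -> float:
        c = float(concentration_um)
        if c < 0:
            raise ValueError("concentration must be non-negative")
        if c == 0.0:
            return 0.0
        if self.ec50_um == 0.0:
            return self.pmax
        return self.pmax * c / (c + self.ec50_um)


@dataclass(frozen=True)
class DrugEffectModel:
    """Concentration-dependent action of one compound on the transient shape."""

    ctd90: EffectCurve | None = None
    br: EffectCurve | None = None
    amp: EffectCurve | None = None
    ead: ProbCurve | None = None
    fibrillation: ProbCurve | None = None
    arrest: ProbCurve | None = None

    @staticmethod
    def null() -> "DrugEffectModel":
        return DrugEffectModel()


def apply_drug_model(
    shape: TransientShape,
    model: DrugEffectModel,
    concentration_um: float,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[TransientShape, EventFlags]:
    """Perturb a well's transient shape by a drug at one concentration.

    Fractional changes follow the model's saturating curves applied to the
    implied CTD90 (via the decay time constant), the beat rate (via the
    period), and the amplitude.  Event flags are Bernoulli draws from the
    seeded stream at the model's concentration-dependent probabilities.
    Concentration zero returns the shape untouched with all flags false.
    """
    c = float(concentration_um)
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0.0:
        return shape, EventFlags()

    new = shape
    if model.ctd90 is not None:
        f = model.ctd90.effect(c)
        target = shape.implied_ctd90_ms * (1.0 + f)
        rise_part = RISE_TO_PEAK_TAU * shape.upstroke_time_constant_ms
        tau_d = max((target - rise_part) / LN10, 5.0)
        new = replace(new, decay_time_constant_ms=tau_d)
    if model.br is not None:
        f = model.br.effect(c)
        new = replace(new, period_ms=shape.period_ms / max(1.0 + f, 0.05))
    if model.amp is not None:
        f = model.amp.effect(c)
        new = replace(new, amplitude=max(shape.amplitude * (1.0 + f), 1e-6))
    # a transient cannot outlast the beating cycle: an over-prolonged
    # transient delays the next spontaneous beat (rate slows) rather than
    # being truncated
    if new.implied_ctd90_ms > 0.8 * new.period_ms:
        new = replace(new, period_ms=new.implied_ctd90_ms / 0.8)

    rng = np.random.default_rng(seed)
    # consume the stream in a fixed order so flags are reproducible
    draws = rng.uniform(size=3)
    flags = EventFlags(
        ead=bool(model.ead is not None and draws[0] < model.ead.prob(c)),
        fibrillation=bool(
            model.fibrillation is not None and draws[1] < model.fibrillation.prob(c)
        ),
        arrest=bool(model.arrest is not None and draws[2] < model.arrest.prob(c)),
    )
    return new, flags


@dataclass(frozen=True)
class BaselineDistributions:
    """Well-to-well heterogeneity of spontaneous beating at baseline.

    Beat rate is truncated-normal (most wells inside the 30–90 beats/min QC
    band); CTD90 is normal, truncated to stay physiologic and shorter than
    the beating cycle.
    """

    br_mean: float = 60.0
    br_sd: float = 12.0
    br_bounds: tuple[float, float] = (20.0, 110.0)
    ctd90_mean_ms: float = 500.0
    ctd90_sd_ms: float = 80.0
    ctd90_min_ms: float = 150.0
    amplitude_mean: float = 1000.0
    amplitude_sd: float = 120.0
    baseline_level: float = 100.0
    noise_sd: float = 8.0
    upstroke_time_constant_ms: float = 10.0

    def draw_shape(self, rng: np.random.Generator) -> TransientShape:
        lo, hi = self.br_bounds
        a, b = (lo - self.br_mean) / self.br_sd, (hi - self.br_mean) / self.br_sd
        br = float(truncnorm.rvs(a, b, loc=self.br_mean, scale=self.br_sd, random_state=rng))
        period = 60000.0 / br
        ctd90 = float(
            np.clip(
                rng.normal(self.ctd90_mean_ms, self.ctd90_sd_ms),
                self.ctd90_min_ms,
                0.85 * period,
            )
        )
        amp = max(float(rng.normal(self.amplitude_mean, self.amplitude_sd)), 50.0)
        return TransientShape.from_ctd90(
            ctd90_ms=ctd90,
            beat_rate=br,
            amplitude=amp,
            baseline_level=self.baseline_level,
            upstroke_time_constant_ms=self.upstroke_time_constant_ms,
            noise_sd=self.noise_sd,
        )


@dataclass(frozen=True)
class PlateSimConfig:
    """Recording-session settings for a simulated plate.

    Durations default to the assay protocol (3-min baseline, 5-min
    post-compound recordings); analyses only use the final minute, so tests
    may shorten them without changing any derived statistic.  Vehicle drift
    is the per-well, per-parameter Δ% perturbation (sd in percentage points)
    that every well acquires between baseline and the post recordings.
    """

    sampling_rate_hz: float = 66.7
    duration_baseline_s: float = 180.0
    duration_post_s: float = 300.0
    vehicle_drift_sd_pct: float = 3.0
    arrest_after_s: float = 8.0
    fibrillation_tail_s: float = 35.0
    phases: tuple[str, ...] = PHASES
    non_synchronous_prob: float = 0.0


def vehicle_layout(n_wells: int = 96, compound: str = "vehicle") -> dict[str, Treatment]:
    """All-vehicle layout on the first n wells of a 96-well plate."""
    from .plate import well_ids_96

    ids = well_ids_96()[:n_wells]
    return {w: Treatment(compound, 0.0, "vehicle") for w in ids}


def control_plate_layout(
    test_compounds: Mapping[str, Sequence[float]] | None = None,
    n_vehicle: int = 8,
    n_per_control: int = 4,
    n_per_test: int = 6,
    controls: Mapping[str, float] | None = None,
) -> dict[str, Treatment]:
    """Typical screening layout: vehicle, positive controls, test series.

    ``controls`` maps control compound name → concentration (μM); defaults
    to the three plate-acceptance controls (hERG blocker at 3 nM,
    beta-agonist at 0.1 μM, calcium antagonist at 0.1 μM).
    """
    from .plate import well_ids_96

    if controls is None:
        controls = {"dofetilide": 0.003, "isoprenaline": 0.1, "nimodipine": 0.1}
    ids = well_ids_96()
    layout: dict[str, Treatment] = {}
    cursor = 0
    for _ in range(n_vehicle):
        layout[ids[cursor]] = Treatment("vehicle", 0.0, "vehicle")
        cursor += 1
    for name, conc in controls.items():
        for _ in range(n_per_control):
            layout[ids[cursor]] = Treatment(name, conc, "positive_control")
            cursor += 1
    for name, concs in (test_compounds or {}).items():
        for conc in concs:
            for _ in range(n_per_test):
                if cursor >= len(ids):
                    raise ValueError("layout exceeds 96 wells")
                layout[ids[cursor]] = Treatment(name, conc, "test")
                cursor += 1
    return layout


def _well_seeds(seed: int, wells: Sequence[str]) -> dict[str, np.random.SeedSequence]:
    """One child SeedSequence per well, keyed by sorted well id."""
    children = np.random.SeedSequence(seed).spawn(len(wells))
    return dict(zip(sorted(wells), children))


def generate_plate(
    layout: Mapping[str, Treatment],
    models: Mapping[str, DrugEffectModel] | None = None,
    baseline: BaselineDistributions | None = None,
    seed: int = 0,
    config: PlateSimConfig | None = None,
    plate_id: str = "plate",
) -> PlateDataset:
    """Simulate a full plate dataset from a layout and drug-effect models.

    Every treated (non-vehicle) compound must have an entry in ``models``.
    Vehicle wells receive only the seeded drift.  The same master seed
    always yields the identical dataset.
    """
    if not isinstance(layout, Mapping):
        pairs = list(layout)
        wells = [w for w, _ in pairs]
        dupes = {w for w in wells if wells.count(w) > 1}
        if dupes:
            raise ValueError(f"layout references wells more than once: {sorted(dupes)}")
        layout = dict(pairs)
    if not layout:
        raise ValueError("layout must contain at least one well")
    baseline = baseline or BaselineDistributions()
    config = config or PlateSimConfig()
    models = dict(models or {})

    for well, trt in layout.items():
        if trt.role != "vehicle" and trt.compound not in models:
            raise ValueError(f"no drug-effect model for compound {trt.compound!r} (well {well})")

    seeds = _well_seeds(seed, list(layout))
    recordings: dict[str, dict[str, TraceRecording]] = {}
    annotations: dict[str, list[str]] = {}
    truth: dict[str, dict] = {}

    for well in sorted(layout):
        trt = layout[well]
        ss = seeds[well]
        # independent child streams per purpose, fixed order
        s_shape, s_drift, s_flags, s_events, s_b, s_p15, s_p30 = ss.spawn(7)
        rng_shape = np.random.default_rng(s_shape)
        base_shape = baseline.draw_shape(rng_shape)
        non_sync = (
            config.non_synchronous_prob > 0
            and rng_shape.uniform() < config.non_synchronous_prob
        )
        if non_sync:
            annotations.setdefault(well, []).append("non_synchronous")

        rng_drift = np.random.default_rng(s_drift)
        drift = rng_drift.normal(0.0, config.vehicle_drift_sd_pct / 100.0, size=3)
        drifted = _apply_fractions(base_shape, drift)

        if trt.role == "vehicle":
            post_shape, flags = drifted, EventFlags()
        else:
            post_shape, flags = apply_drug_model(
                drifted, models[trt.compound], trt.concentration_um, s_flags
            )

        events = _realize_events(
            post_shape, flags, config, np.random.default_rng(s_events),
            duration_s=config.duration_post_s,
        )

        well_rec: dict[str, TraceRecording] = {}
        if "baseline" in config.phases:
            well_rec["baseline"] = render_trace(
                base_shape, config.duration_baseline_s, config.sampling_rate_hz,
                seed=s_b, phase="baseline",
            )
        for ph, s_ph in (("post15", s_p15), ("post30", s_p30)):
            if ph in config.phases:
                well_rec[ph] = render_trace(
                    post_shape, config.duration_post_s, config.sampling_rate_hz,
                    seed=s_ph, events=events, phase=ph,
                )
        recordings[well] = well_rec
        truth[well] = {
            "baseline_shape": base_shape,
            "post_shape": post_shape,
            "flags": flags,
            "drift_fractions": drift,
        }

    return PlateDataset(
        layout=dict(layout),
        recordings=recordings,
        sampling_rate_hz=config.sampling_rate_hz,
        seed=seed,
        plate_id=plate_id,
        annotations=annotations,
        truth=truth,
    )


def _apply_fractions(shape: TransientShape, fractions: np.ndarray) -> TransientShape:
    """Apply (ctd90, br, amp) fractional drifts to a shape."""
    f_ctd, f_br, f_amp = (float(x) for x in fractions)
    rise_part = RISE_TO_PEAK_TAU * shape.upstroke_time_constant_ms
    tau_d = max((shape.implied_ctd90_ms * (1.0 + f_ctd) - rise_part) / LN10, 5.0)
    out = replace(
        shape,
        decay_time_constant_ms=tau_d,
        period_ms=shape.period_ms / max(1.0 + f_br, 0.05),
        amplitude=max(shape.amplitude * (1.0 + f_amp), 1e-6),
    )
    if out.implied_ctd90_ms > 0.9 * out.period_ms:
        out = replace(out, period_ms=out.implied_ctd90_ms / 0.9)
    return out


def _realize_events(
    shape: TransientShape,
    flags: EventFlags,
    config: PlateSimConfig,
    rng: np.random.Generator,
    duration_s: float,
    first_beat_time_s: float = 0.3,
) -> TraceEvents:
    """Turn event flags into concrete render instructions for a post phase.

    EAD spikes are injected onto the decay phase of randomly chosen beats in
    the final-minute analysis window; fibrillation replaces the tail of the
    recording; arrest truncates beating early so the final window is flat.
    """
    if not flags.any():
        return TraceEvents()
    if flags.arrest:
        return TraceEvents(arrest_after_s=config.arrest_after_s)
    fib = None
    fib_start = duration_s - config.fibrillation_tail_s
    if flags.fibrillation:
        fib = (fib_start, float(rng.uniform(3.2, 4.0)), float(rng.uniform(0.15, 0.25)))
    spikes: list[tuple[float, float]] = []
    if flags.ead:
        period_s = shape.period_ms / 1000.0
        rise_s = shape.rise_duration_ms / 1000.0
        ctd90_s = shape.implied_ctd90_ms / 1000.0
        onsets = np.arange(first_beat_time_s, duration_s, period_s)
        lo = duration_s - 58.0
        hi = (fib_start if fib is not None else duration_s) - 2.0 * period_s
        candidates = onsets[(onsets >= lo) & (onsets < hi)]
        if candidates.size:
            n_spikes = min(int(rng.integers(1, 4)), candidates.size)
            chosen = rng.choice(candidates, size=n_spikes, replace=False)
            for onset in sorted(float(o) for o in chosen):
                spike_t = onset + rise_s + float(rng.uniform(0.35, 0.55)) * ctd90_s
                spikes.append((spike_t, float(rng.uniform(0.25, 0.45))))
    return TraceEvents(ead_spikes=tuple(spikes), fibrillation=fib)
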