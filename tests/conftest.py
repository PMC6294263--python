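"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


# --- independent continuous-waveform CTD90 oracle -----------------------
#
# Evaluates the transient waveform (logistic upstroke over 8 time constants
# rescaled to [0, 1], then exponential decay) in continuous time on a fine
# grid, at periodic steady state (including the decaying tails of previous
# beats), and applies the duration definition directly: time from the
# upward crossing of 10% amplitude to the first post-peak downward crossing
# of the same level.  Shares no code with the sampled-trace pipeline.

def _oracle_kernel(s: np.ndarray, tau_up: float, tau_d: float) -> np.ndarray:
    rise = 8.0 * tau_up
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
    lo, hi = sig(np.array(-4.0)), sig(np.array(4.0))
    out = np.where(
        s < rise,
        (sig((s - 4.0 * tau_up) / tau_up) - lo) / (hi - lo),
        np.exp(-np.maximum(s - rise, 0.0) / tau_d),
    )
    return np.where(s < 0, 0.0, out)


def analytic_ctd90_ms(shape, dt_ms: float = 0.05, n_history: int = 30) -> float:
    """Steady-state CTD90 (ms) of the continuous periodic waveform."""
    period = shape.period_ms
    tau_up = shape.upstroke_time_constant_ms
    tau_d = shape.decay_time_constant_ms
    t = np.arange(0.0, period, dt_ms)
    y = np.zeros_like(t)
    for k in range(n_history + 1):
        y += _oracle_kernel(t + k * period, tau_up, tau_d)
    base = float(y.min())
    peak = float(y.max())
    ip = int(y.argmax())
    level = base + 0.10 * (peak - base)

    # upward crossing before the peak
    rise_idx = None
    for i in range(ip, 0, -1):
        if y[i - 1] <= level < y[i]:
            rise_idx = i
            break
    assert rise_idx is not None, "no rise crossing found"
    fr = (level - y[rise_idx - 1]) / (y[rise_idx] - y[rise_idx - 1])
    t_rise = (rise_idx - 1 + fr) * dt_ms

    # downward crossing after the peak (may wrap into the next cycle's tail)
    yy = np.concatenate([y, y])
    fall_idx = None
    for i in range(ip + 1, yy.size):
        if yy[i] <= level < yy[i - 1]:
            fall_idx = i
            break
    assert fall_idx is not None, "no decay crossing found"
    fr = (yy[fall_idx - 1] - level) / (yy[fall_idx - 1] - yy[fall_idx])
    t_fall = (fall_idx - 1 + fr) * dt_ms
    return t_fall - t_rise


# closed-form Wilks confidence for the (min, max) interval:
# P(coverage >= p) = 1 - n p^{n-1} + (n-1) p^n  (Beta(n-1,2) upper tail)
def wilks_confidence_closed_form(n: int, p: float) -> float:
    return 1.0 - n * p ** (n - 1) + (n - 1) * p**n


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_shape():
    """Noise-free, well-separated transients: BR 60, CTD90 ≈ 460.5 ms."""
    from cthazard.simulate import TransientShape

    return TransientShape(
        amplitude=1000.0,
        upstroke_time_constant_ms=1.0,
        decay_time_constant_ms=200.0,
        period_ms=1500.0,
        noise_sd=0.0,
    )


def severity(label: str) -> int:
    return ("no", "low", "high", "very_high").index(label)
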