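"""Nonparametric (Wilks) tolerance intervals and scoring-matrix cutoff derivation.

A two-sided Wilks tolerance interval is formed from the sample extremes
(min, max).  The population proportion covered by that interval follows a
Beta(n-1, 2) law regardless of the sampled distribution, so the achieved
confidence that the interval covers at least a proportion ``p`` of the
population is ``P(Beta(n-1, 2) >= p)``.  Here the intervals characterise
per-plate Δ% effect distributions of vehicle and control-drug treatments;
re-centering the control intervals by the vehicle interval midpoint turns
them into ΔΔ% cutoffs for the hazard scoring matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta as _beta

__all__ = [
    "ToleranceInterval",
    "DirectionCutoffs",
    "CutoffSet",
    "wilks_ti",
    "achieved_confidence",
    "min_sample_size",
    "derive_cutoffs",
]

PARAMETERS = ("ctd90", "br", "amp")


@dataclass(frozen=True)
class ToleranceInterval:
    """Two-sided order-statistic tolerance interval from sample extremes."""

    lower: float
    upper: float
    coverage_p: float
    confidence_gamma: float
    n: int
    achieved_confidence: float
    insufficient_n: bool = False

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


def achieved_confidence(n: int, coverage_p: float) -> float:
    """Confidence that the (min, max) interval of an n-sample covers >= p.

    The inter-extreme coverage of an i.i.d. continuous sample is
    Beta(n-1, 2)-distributed, so this is the upper tail of that law at p.
    """
    if n < 2:
        raise ValueError("tolerance interval requires n >= 2")
    if not 0.0 < coverage_p < 1.0:
        raise ValueError("coverage_p must lie in (0, 1)")
    return float(_beta.sf(coverage_p, n - 1, 2))


def wilks_ti(
    samples: Sequence[float],
    coverage_p: float = 0.90,
    confidence_gamma: float = 0.95,
) -> ToleranceInterval:
    """Two-sided Wilks tolerance interval (sample min, sample max).

    Parameters
    ----------
    samples
        Observed values (e.g. per-well Δ% effects). Must be finite, n >= 2.
    coverage_p
        Population proportion the interval is meant to cover.
    confidence_gamma
        Required confidence level. If the sample is too small to reach it,
        the interval is still returned but flagged ``insufficient_n``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("wilks_ti requires at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("wilks_ti requires finite samples")
    if not 0.0 < confidence_gamma < 1.0:
        raise ValueError("confidence_gamma must lie in (0, 1)")
    conf = achieved_confidence(int(x.size), coverage_p)
    return ToleranceInterval(
        lower=float(x.min()),
        upper=float(x.max()),
        coverage_p=coverage_p,
        confidence_gamma=confidence_gamma,
        n=int(x.size),
        achieved_confidence=conf,
        insufficient_n=conf < confidence_gamma,
    )


def min_sample_size(coverage_p: float, confidence_gamma: float) -> int:
    """Smallest n whose (min, max) interval reaches the required confidence.

    Scans n upward; the achieved confidence is monotone increasing in n for
    fixed p, so the first hit is the minimum.
    """
    if not (0.0 < coverage_p < 1.0 and 0.0 < confidence_gamma < 1.0):
        raise ValueError("coverage_p and confidence_gamma must lie in (0, 1)")
    n = 2
    while achieved_confidence(n, coverage_p) < confidence_gamma:
        n += 1
    return n


@dataclass(frozen=True)
class DirectionCutoffs:
    """Zone boundaries for one parameter, ΔΔ% scale, both directions.

    Zones partition the real line:

        (-inf, strong_down) | [strong_down, mild-) ... boundary rule:
        a value exactly on a boundary belongs to the *milder* zone.

    ``no_effect_low <= 0 <= no_effect_high``;
    ``strong_down < mild_down <= no_effect_low`` and symmetrically upward.
    A direction without a strong cutoff (no control available) may carry
    ``None`` there, in which case everything beyond mild stays mild.
    """

    no_effect_low: float
    no_effect_high: float
    mild_down: float | None = None
    mild_up: float | None = None
    strong_down: float | None = None
    strong_up: float | None = None

    def zone(self, dd_percent: float) -> str:
        """Zone name for a ΔΔ% value; boundaries belong to the milder zone."""
        x = float(dd_percent)
        if not math.isfinite(x):
            raise ValueError("ΔΔ% must be finite")
        if self.no_effect_low <= x <= self.no_effect_high:
            return "no_effect"
        if x > self.no_effect_high:
            if self.strong_up is not None and x > self.strong_up:
                return "strong_up"
            return "mild_up"
        if self.strong_down is not None and x < self.strong_down:
            return "strong_down"
        return "mild_down"


@dataclass(frozen=True)
class CutoffSet:
    """Per-parameter ΔΔ% zone boundaries for the scoring matrix."""

    parameters: Mapping[str, DirectionCutoffs] = field(default_factory=dict)

    def __getitem__(self, parameter: str) -> DirectionCutoffs:
        return self.parameters[parameter]

    def to_dict(self) -> dict:
        out: dict = {}
        for name, c in self.parameters.items():
            out[name] = {
                "no_effect_low": c.no_effect_low,
                "no_effect_high": c.no_effect_high,
                "mild_down": c.mild_down,
                "mild_up": c.mild_up,
                "strong_down": c.strong_down,
                "strong_up": c.strong_up,
            }
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "CutoffSet":
        return cls(
            parameters={
                name: DirectionCutoffs(**{k: v for k, v in spec.items()})
                for name, spec in d.items()
            }
        )


def _mild_bound(no_effect_bound: float, strong_bound: float, rule: str) -> float:
    if rule == "midpoint":
        return 0.5 * (no_effect_bound + strong_bound)
    raise ValueError(f"unknown mild-cutoff rule: {rule!r}")


def derive_cutoffs(
    vehicle_samples: Mapping[str, Sequence[float]],
    control_samples: Mapping[tuple[str, str], Sequence[float]],
    coverage_p: float = 0.90,
    confidence_gamma: float = 0.95,
    mild_rule: str = "midpoint",
    mild_bounds: Mapping[tuple[str, str], float] | None = None,
) -> CutoffSet:
    """Turn vehicle and control-drug Δ% samples into ΔΔ% scoring cutoffs.

    For each parameter the vehicle tolerance interval, re-centered at zero
    (both bounds minus the interval midpoint), gives the no-effect zone.
    For each (parameter, direction) with a control sample, the strong cutoff
    is the control interval's bound on the far side of the direction of
    action ("up" → upper bound, "down" → lower bound), minus the vehicle
    midpoint.  Mild cutoffs sit strictly between the two, by default at the
    midpoint, unless supplied explicitly via ``mild_bounds``.

    Parameters
    ----------
    vehicle_samples
        Parameter name → vehicle Δ% values. Each sample should satisfy
        ``min_sample_size(coverage_p, confidence_gamma)``; smaller samples
        produce flagged (insufficient-n) intervals but still derive cutoffs.
    control_samples
        (parameter, direction) → control-drug Δ% values, direction in
        {"up", "down"} declaring the control's direction of action.
    mild_bounds
        Optional explicit mild cutoffs, same keying as ``control_samples``.

    Raises
    ------
    ValueError
        If a control's strong cutoff falls inside the no-effect zone (the
        control is too weak to define a strong boundary).
    """
    cutoffs: dict[str, DirectionCutoffs] = {}
    for parameter, veh in vehicle_samples.items():
        veh_ti = wilks_ti(veh, coverage_p, confidence_gamma)
        mid = veh_ti.midpoint
        no_low = veh_ti.lower - mid
        no_high = veh_ti.upper - mid

        strong: dict[str, float | None] = {"up": None, "down": None}
        mild: dict[str, float | None] = {"up": None, "down": None}
        for direction in ("up", "down"):
            key = (parameter, direction)
            if key not in control_samples:
                continue
            ctrl_ti = wilks_ti(control_samples[key], coverage_p, confidence_gamma)
            bound = ctrl_ti.upper if direction == "up" else ctrl_ti.lower
            strong_bound = bound - mid
            no_bound = no_high if direction == "up" else no_low
            inside = (
                strong_bound <= no_bound if direction == "up" else strong_bound >= no_bound
            )
            if inside:
                raise ValueError(
                    f"control for {parameter}/{direction} is too weak: strong cutoff "
                    f"{strong_bound:.2f} falls inside the no-effect zone "
                    f"[{no_low:.2f}, {no_high:.2f}]"
                )
            strong[direction] = strong_bound
            if mild_bounds is not None and key in mild_bounds:
                mb = float(mild_bounds[key])
                lo, hi = sorted((no_bound, strong_bound))
                if not lo < mb < hi:
                    raise ValueError(
                        f"explicit mild cutoff {mb} for {parameter}/{direction} must lie "
                        f"strictly between no-effect ({no_bound}) and strong ({strong_bound})"
                    )
                mild[direction] = mb
            else:
                mild[direction] = _mild_bound(no_bound, strong_bound, mild_rule)

        cutoffs[parameter] = DirectionCutoffs(
            no_effect_low=no_low,
            no_effect_high=no_high,
            mild_up=mild["up"],
            mild_down=mild["down"],
            strong_up=strong["up"],
            strong_down=strong["down"],
        )
    return CutoffSet(parameters=cutoffs)
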