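"""Weighted hazard scoring matrix: points per parameter, total score, label.

Each study (one compound at one concentration on one plate) is scored by
placing its net ΔΔ% effect on every beating parameter into a zone
(no-effect / mild / strong, per direction), awarding that zone's weighted
points, adding incidence points for beating arrest (three incidence zones)
and fibrillation-like events, and mapping the summed score to a hazard
label: no (green), low (yellow) or high (red).  Studies with any EAD-like
event are uniquely categorized as very-high (black) hazard regardless of
the numeric score — EADs are the assay's torsadogenic surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .effects import StudyEffect
from .tolerance import CutoffSet, DirectionCutoffs

__all__ = [
    "LABELS",
    "LABEL_COLORS",
    "ParameterSpec",
    "BeatStopZones",
    "LabelRange",
    "ScoringMatrix",
    "HazardResult",
    "score_parameter",
    "score_incidence",
    "score_study",
    "rank_compounds",
    "default_weights",
]

LABELS = ("no", "low", "high", "very_high")
LABEL_COLORS = {"no": "green", "low": "yellow", "high": "red", "very_high": "black"}
_SEVERITY = {label: i for i, label in enumerate(LABELS)}

ZONES = ("no_effect", "mild_down", "mild_up", "strong_down", "strong_up")


@dataclass(frozen=True)
class ParameterSpec:
    """Zone boundaries and weighted points for one beating parameter."""

    cutoffs: DirectionCutoffs
    points: Mapping[str, int]  # zone name -> points; no_effect must map to 0

    def validate(self, name: str = "") -> None:
        pts = dict(self.points)
        if set(pts) - set(ZONES):
            raise ValueError(f"{name}: unknown zones {set(pts) - set(ZONES)}")
        for zone in ZONES:
            if zone not in pts:
                raise ValueError(f"{name}: missing points for zone {zone}")
            if not isinstance(pts[zone], int):
                raise ValueError(f"{name}: points must be integers ({zone})")
        if pts["no_effect"] != 0:
            raise ValueError(f"{name}: no_effect zone must score 0 points")
        for d in ("up", "down"):
            if abs(pts[f"strong_{d}"]) < abs(pts[f"mild_{d}"]):
                raise ValueError(f"{name}: strong_{d} points must dominate mild_{d}")


@dataclass(frozen=True)
class BeatStopZones:
    """Three beat-stop incidence zones (plus zero incidence scoring 0).

    Partial arrest up to ``partial_boundary`` (inclusive) is the mild zone —
    limited incidences occur even with relatively cardiac-safe sodium
    blockers; higher partial incidence is the middle zone; complete (100%)
    arrest is its own zone, severe enough to reach a high label alone.
    """

    partial_boundary: float = 0.5
    points_partial_low: int = 1
    points_partial_high: int = 2
    points_complete: int = 4

    def score(self, incidence: float) -> int:
        if not 0.0 <= incidence <= 1.0:
            raise ValueError("incidence must lie in [0, 1]")
        if incidence == 0.0:
            return 0
        if incidence <= self.partial_boundary:
            return self.points_partial_low
        if incidence < 1.0:
            return self.points_partial_high
        return self.points_complete


@dataclass(frozen=True)
class LabelRange:
    """Total-score interval mapped to a hazard label (max None = unbounded)."""

    min_score: int
    max_score: int | None
    label: str


def default_weights() -> dict[str, dict[str, int]]:
    """Default weighted points: CTD90 dominates, BR and Amp are secondary."""
    return {
        "ctd90": {"no_effect": 0, "mild_down": 1, "mild_up": 1, "strong_down": 3, "strong_up": 3},
        "br": {"no_effect": 0, "mild_down": 1, "mild_up": 1, "strong_down": 2, "strong_up": 2},
        "amp": {"no_effect": 0, "mild_down": 1, "mild_up": 1, "strong_down": 2, "strong_up": 2},
    }


def default_label_ranges() -> tuple[LabelRange, ...]:
    return (
        LabelRange(0, 0, "no"),
        LabelRange(1, 2, "low"),
        LabelRange(3, None, "high"),
    )


@dataclass
class ScoringMatrix:
    """The full scoring configuration: cutoffs, weights, incidences, labels."""

    parameters: dict[str, ParameterSpec]
    beat_stop: BeatStopZones = field(default_factory=BeatStopZones)
    fibrillation_points: int = 4
    label_ranges: tuple[LabelRange, ...] = field(default_factory=default_label_ranges)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.parameters:
            raise ValueError("scoring matrix needs at least one parameter")
        for name, spec in self.parameters.items():
            spec.validate(name)
        if not isinstance(self.fibrillation_points, int) or self.fibrillation_points < 0:
            raise ValueError("fibrillation points must be a non-negative integer")
        ranges = sorted(self.label_ranges, key=lambda r: r.min_score)
        if ranges[0].min_score != 0:
            raise ValueError("label ranges must start at score 0")
        for prev, cur in zip(ranges, ranges[1:]):
            if prev.max_score is None or cur.min_score != prev.max_score + 1:
                raise ValueError("label ranges must partition scores without gaps/overlap")
        if ranges[-1].max_score is not None:
            raise ValueError("last label range must be unbounded")
        for r in ranges:
            if r.label not in ("no", "low", "high"):
                raise ValueError(f"label {r.label!r} not assignable by score")
        # higher totals never map to a milder label
        sev = [_SEVERITY[r.label] for r in ranges]
        if sev != sorted(sev):
            raise ValueError("label severity must be nondecreasing with score")

    def label_for(self, total: int) -> str:
        for r in sorted(self.label_ranges, key=lambda x: x.min_score):
            if total >= r.min_score and (r.max_score is None or total <= r.max_score):
                return r.label
        raise ValueError(f"total score {total} outside label ranges")

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parameters": {
                name: {
                    "cutoffs": {
                        "no_effect_low": spec.cutoffs.no_effect_low,
                        "no_effect_high": spec.cutoffs.no_effect_high,
                        "mild_down": spec.cutoffs.mild_down,
                        "mild_up": spec.cutoffs.mild_up,
                        "strong_down": spec.cutoffs.strong_down,
                        "strong_up": spec.cutoffs.strong_up,
                    },
                    "points": dict(spec.points),
                }
                for name, spec in self.parameters.items()
            },
            "beat_stop": {
                "partial_boundary": self.beat_stop.partial_boundary,
                "points_partial_low": self.beat_stop.points_partial_low,
                "points_partial_high": self.beat_stop.points_partial_high,
                "points_complete": self.beat_stop.points_complete,
            },
            "fibrillation_points": self.fibrillation_points,
            "label_ranges": [
                {"min_score": r.min_score, "max_score": r.max_score, "label": r.label}
                for r in self.label_ranges
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringMatrix":
        required = {"parameters", "beat_stop", "fibrillation_points", "label_ranges"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"scoring-matrix config missing keys: {sorted(missing)}")
        params = {
            name: ParameterSpec(
                cutoffs=DirectionCutoffs(**spec["cutoffs"]),
                points={k: int(v) for k, v in spec["points"].items()},
            )
            for name, spec in d["parameters"].items()
        }
        return cls(
            parameters=params,
            beat_stop=BeatStopZones(**d["beat_stop"]),
            fibrillation_points=int(d["fibrillation_points"]),
            label_ranges=tuple(LabelRange(**r) for r in d["label_ranges"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ScoringMatrix":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_cutoffs(
        cls,
        cutoffs: CutoffSet,
        weights: Mapping[str, Mapping[str, int]] | None = None,
        **kwargs,
    ) -> "ScoringMatrix":
        weights = weights or default_weights()
        params = {
            name: ParameterSpec(cutoffs=c, points=dict(weights[name]))
            for name, c in cutoffs.parameters.items()
        }
        return cls(parameters=params, **kwargs)


@dataclass
class HazardResult:
    """Hazard call for one compound-concentration study."""

    compound: str
    concentration_um: float
    total_score: int
    label: str
    breakdown: dict[str, dict] = field(default_factory=dict)
    override_applied: bool = False
    plate_id: str = "plate"

    @property
    def color(self) -> str:
        return LABEL_COLORS[self.label]


def score_parameter(
    dd_percent: float | None, spec: ParameterSpec
) -> tuple[int, str]:
    """Points and zone for one parameter's ΔΔ% (None → not evaluable, 0 pts)."""
    if dd_percent is None:
        return 0, "not_evaluable"
    if not math.isfinite(dd_percent):
        raise ValueError("ΔΔ% must be finite")
    zone = spec.cutoffs.zone(dd_percent)
    return int(spec.points[zone]), zone


def score_incidence(
    beat_stop_incidence: float,
    fibrillation_incidence: float,
    matrix: ScoringMatrix,
) -> tuple[int, dict]:
    """Points from beating-arrest and fibrillation incidences."""
    if not 0.0 <= fibrillation_incidence <= 1.0:
        raise ValueError("incidence must lie in [0, 1]")
    bs = matrix.beat_stop.score(beat_stop_incidence)
    fib = matrix.fibrillation_points if fibrillation_incidence > 0 else 0
    return bs + fib, {"beat_stop": bs, "fibrillation": fib}


def score_study(effect: StudyEffect, matrix: ScoringMatrix) -> HazardResult:
    """Score one study: parameter points + incidence points → label.

    Refuses QC-failed input.  A study with 100% arrest carries no parameter
    ΔΔ% and is scored from incidence points alone.  Any EAD incidence
    overrides the label to very_high.
    """
    if not effect.qc_passed:
        raise ValueError(
            f"study {effect.compound}@{effect.concentration_um} uM is on a QC-failed "
            "plate; scoring excluded plates is forbidden"
        )
    breakdown: dict[str, dict] = {}
    total = 0
    for name, spec in matrix.parameters.items():
        pts, zone = score_parameter(effect.dd.get(name), spec)
        breakdown[name] = {"points": pts, "zone": zone, "dd_percent": effect.dd.get(name)}
        total += pts
    inc_pts, inc_detail = score_incidence(
        effect.beat_stop_incidence, effect.fibrillation_incidence, matrix
    )
    breakdown["incidence"] = {
        "points": inc_pts,
        **inc_detail,
        "beat_stop_incidence": effect.beat_stop_incidence,
        "fibrillation_incidence": effect.fibrillation_incidence,
    }
    total += inc_pts

    override = effect.ead_incidence > 0
    label = "very_high" if override else matrix.label_for(total)
    return HazardResult(
        compound=effect.compound,
        concentration_um=effect.concentration_um,
        total_score=total,
        label=label,
        breakdown=breakdown,
        override_applied=override,
        plate_id=effect.plate_id,
    )


def rank_compounds(results: Sequence[HazardResult]) -> pd.DataFrame:
    """Concentration-dependent hazard table, worst compounds first.

    Rows are ordered by compound rank — worst label reached, then the lowest
    concentration at which it is reached, then compound id — and within a
    compound by ascending concentration.
    """
    seen = set()
    for r in results:
        key = (r.compound, r.concentration_um)
        if key in seen:
            raise ValueError(f"duplicate compound-concentration entry: {key}")
        seen.add(key)

    by_compound: dict[str, list[HazardResult]] = {}
    for r in results:
        by_compound.setdefault(r.compound, []).append(r)

    def compound_key(compound: str):
        rs = by_compound[compound]
        worst = max(_SEVERITY[r.label] for r in rs)
        lowest_conc = min(r.concentration_um for r in rs if _SEVERITY[r.label] == worst)
        return (-worst, lowest_conc, compound)

    rows = []
    for compound in sorted(by_compound, key=compound_key):
        for r in sorted(by_compound[compound], key=lambda x: x.concentration_um):
            rows.append(
                {
                    "compound": r.compound,
                    "concentration_um": r.concentration_um,
                    "total_score": r.total_score,
                    "label": r.label,
                    "color": r.color,
                    "override_applied": r.override_applied,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "compound", "concentration_um", "total_score", "label", "color", "override_applied",
        ],
    )
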