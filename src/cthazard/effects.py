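"""Vehicle-normalized drug effects and plate quality control.

Per-well effects are percent changes at 30 min relative to baseline
(Δ% = 100·(x₃₀ − x₀)/x₀) for CTD90, beat rate and amplitude.  Per plate and
treatment, well Δ% values are aggregated by the median (typically 4–8 wells)
and corrected for the same plate's vehicle median, giving the net effect
ΔΔ% = Δ%(drug) − Δ%(vehicle).  Abnormal phenotypes enter as incidences: the
fraction of a treatment's wells showing beating arrest, EAD-like spikes, or
fibrillation-like activity.

Quality control follows the assay's acceptance rules: wells with no beating
or non-synchronous beating at baseline, or baseline beat rate outside
30–90 beats/min, are excluded; a plate is rejected when more than 10% of
its wells violate the beat-rate criteria or when a positive-control
treatment fails its expected-response criterion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import WellSummary
from .plate import Treatment

__all__ = [
    "PARAMETERS",
    "UndefinedEffectError",
    "AggregationError",
    "NormalizationError",
    "WellEffect",
    "StudyEffect",
    "PlateQCReport",
    "PositiveControlCriterion",
    "QCConfig",
    "delta_percent",
    "delta_delta",
    "apply_well_qc",
    "compute_well_effects",
    "aggregate_treatment",
    "apply_plate_qc",
]

logger = logging.getLogger(__name__)

PARAMETERS = ("ctd90", "br", "amp")


class UndefinedEffectError(ValueError):
    """Δ% is undefined (non-positive baseline value)."""


class AggregationError(ValueError):
    """No included wells to aggregate."""


class NormalizationError(ValueError):
    """Vehicle reference unavailable for ΔΔ% correction."""


def delta_percent(value_30min: float, value_baseline: float) -> float:
    """Percent change at 30 min versus baseline: 100·(x₃₀ − x₀)/x₀."""
    if not (math.isfinite(value_30min) and math.isfinite(value_baseline)):
        raise UndefinedEffectError("Δ% requires finite values")
    if value_baseline <= 0:
        raise UndefinedEffectError(f"Δ% undefined for baseline {value_baseline!r}")
    return 100.0 * (value_30min - value_baseline) / value_baseline


def delta_delta(drug_median_pct: float, vehicle_median_pct: float | None) -> float:
    """Net effect: treatment median Δ% minus the plate's vehicle median Δ%."""
    if vehicle_median_pct is None or not math.isfinite(vehicle_median_pct):
        raise NormalizationError("vehicle median Δ% unavailable for this plate")
    return float(drug_median_pct) - float(vehicle_median_pct)


@dataclass
class WellEffect:
    """One well's Δ% effects with its QC annotation."""

    well: str
    treatment: Treatment
    delta: dict[str, float | None] = field(default_factory=dict)
    beat_stop: bool = False
    ead: bool = False
    fibrillation: bool = False
    qc_status: str = "included"  # included | excluded
    qc_reason: str | None = None

    @property
    def included(self) -> bool:
        return self.qc_status == "included"


@dataclass
class StudyEffect:
    """Plate-level net effect of one compound at one concentration."""

    compound: str
    concentration_um: float
    dd: dict[str, float | None] = field(default_factory=dict)  # ΔΔ%, per parameter
    delta_median: dict[str, float | None] = field(default_factory=dict)  # Δ% medians
    beat_stop_incidence: float = 0.0
    ead_incidence: float = 0.0
    fibrillation_incidence: float = 0.0
    n_wells: int = 0
    plate_id: str = "plate"
    role: str = "test"
    qc_passed: bool = True
    all_stopped: bool = False


@dataclass(frozen=True)
class PositiveControlCriterion:
    """Plate-acceptance rule on a positive control's expected net response.

    The plate fails when the control's ΔΔ% on ``parameter`` is on the wrong
    side of ``threshold``: for ``fail_when="below"`` a response smaller than
    the threshold rejects the plate (an insensitive plate); for "above", a
    response larger than the threshold rejects it.
    """

    compound: str
    concentration_um: float
    parameter: str
    fail_when: str  # "below" | "above"
    threshold: float
    reason: str

    def triggered(self, dd_value: float | None) -> bool:
        if dd_value is None:
            return True  # control uninterpretable: treat as insensitive
        if self.fail_when == "below":
            return dd_value < self.threshold
        if self.fail_when == "above":
            return dd_value > self.threshold
        raise ValueError(f"unknown fail_when {self.fail_when!r}")


def default_positive_control_criteria() -> tuple[PositiveControlCriterion, ...]:
    """The assay's three plate-acceptance controls.

    A hERG blocker at 3 nM must prolong CTD90 by at least 15 ΔΔ%, a
    beta-agonist at 0.1 μM must raise BR by at least 30 ΔΔ%, and a calcium
    antagonist at 0.1 μM must shorten CTD90 by more than 10 ΔΔ%.
    """
    return (
        PositiveControlCriterion("dofetilide", 0.003, "ctd90", "below", 15.0, "dofetilide_insensitive"),
        PositiveControlCriterion("isoprenaline", 0.1, "br", "below", 30.0, "isoprenaline_insensitive"),
        PositiveControlCriterion("nimodipine", 0.1, "ctd90", "above", -10.0, "nimodipine_insensitive"),
    )


@dataclass(frozen=True)
class QCConfig:
    """Well- and plate-level acceptance thresholds."""

    br_min: float = 30.0  # inclusive: exactly 30 beats/min passes
    br_max: float = 90.0  # inclusive
    max_br_outlier_fraction: float = 0.10
    n_wells_expected: tuple[int, int] = (4, 8)
    positive_controls: tuple[PositiveControlCriterion, ...] = field(
        default_factory=default_positive_control_criteria
    )


@dataclass
class PlateQCReport:
    plate_id: str
    n_wells: int
    well_exclusions: list[tuple[str, str]] = field(default_factory=list)
    br_outlier_fraction: float = 0.0
    plate_pass: bool = True
    plate_fail_reasons: list[str] = field(default_factory=list)


def apply_well_qc(
    baseline_summaries: Mapping[str, WellSummary],
    annotations: Mapping[str, Sequence[str]] | None = None,
    config: QCConfig | None = None,
) -> dict[str, tuple[str, str | None]]:
    """Classify wells as included/excluded from their baseline recording.

    Exclusion reasons: ``no_beating`` (silent at baseline),
    ``br_out_of_range`` (baseline rate strictly below 30 or strictly above
    90 beats/min; the bounds themselves pass), ``non_synchronous`` (an
    upstream annotation — desynchrony is not inferable from the integrated
    whole-well signal).
    """
    config = config or QCConfig()
    annotations = annotations or {}
    out: dict[str, tuple[str, str | None]] = {}
    for well, summary in baseline_summaries.items():
        if "non_synchronous" in annotations.get(well, ()):
            out[well] = ("excluded", "non_synchronous")
        elif summary.n_beats == 0 or summary.beat_rate <= 0:
            out[well] = ("excluded", "no_beating")
        elif summary.beat_rate < config.br_min or summary.beat_rate > config.br_max:
            out[well] = ("excluded", "br_out_of_range")
        else:
            out[well] = ("included", None)
    return out


def compute_well_effects(
    summaries: Mapping[str, Mapping[str, WellSummary]],
    layout: Mapping[str, Treatment],
    qc: Mapping[str, tuple[str, str | None]],
) -> list[WellEffect]:
    """Per-well Δ% effects (30 min vs baseline) with QC annotations.

    A well that arrests by 30 min keeps its phenotype flags but carries no
    parameter Δ% — arrest is scored as an incidence, not as a −100% change.
    """
    effects: list[WellEffect] = []
    for well in sorted(summaries):
        status, reason = qc.get(well, ("included", None))
        phases = summaries[well]
        base, post = phases["baseline"], phases["post30"]
        eff = WellEffect(
            well=well,
            treatment=layout[well],
            beat_stop=post.beat_stop,
            ead=post.ead_detected,
            fibrillation=post.fibrillation_detected,
            qc_status=status,
            qc_reason=reason,
        )
        if status == "included" and not post.beat_stop:
            pairs = {
                "ctd90": (post.ctd90_median_ms, base.ctd90_median_ms),
                "br": (post.beat_rate, base.beat_rate),
                "amp": (post.amplitude_median, base.amplitude_median),
            }
            for param, (v30, v0) in pairs.items():
                if v30 is None or v0 is None or v0 <= 0:
                    eff.delta[param] = None
                else:
                    eff.delta[param] = delta_percent(v30, v0)
        else:
            eff.delta = {param: None for param in PARAMETERS}
        effects.append(eff)
    return effects


def aggregate_treatment(
    well_effects: Sequence[WellEffect],
    plate_id: str = "plate",
    config: QCConfig | None = None,
) -> StudyEffect:
    """Aggregate one plate-treatment's included wells to a study effect.

    Parameter medians are taken over included, still-beating wells; arrested
    wells contribute to the beat-stop incidence but not to the medians.
    Logs a warning when the included-well count falls outside the expected
    4–8 range.
    """
    config = config or QCConfig()
    included = [e for e in well_effects if e.included]
    if not included:
        raise AggregationError("no included wells for treatment")
    treatments = {e.treatment for e in included}
    if len(treatments) != 1:
        raise AggregationError(f"mixed treatments in aggregation: {treatments}")
    trt = included[0].treatment

    lo, hi = config.n_wells_expected
    if not lo <= len(included) <= hi:
        logger.warning(
            "treatment %s@%g uM on %s has %d included wells (expected %d-%d)",
            trt.compound, trt.concentration_um, plate_id, len(included), lo, hi,
        )

    beating = [e for e in included if not e.beat_stop]
    medians: dict[str, float | None] = {}
    for param in PARAMETERS:
        vals = [e.delta[param] for e in beating if e.delta.get(param) is not None]
        medians[param] = float(np.median(vals)) if vals else None

    n = len(included)
    return StudyEffect(
        compound=trt.compound,
        concentration_um=trt.concentration_um,
        delta_median=medians,
        beat_stop_incidence=sum(e.beat_stop for e in included) / n,
        ead_incidence=sum(e.ead for e in included) / n,
        fibrillation_incidence=sum(e.fibrillation for e in included) / n,
        n_wells=n,
        plate_id=plate_id,
        role=trt.role,
        all_stopped=not beating,
    )


def vehicle_reference(study_effects: Sequence[StudyEffect]) -> StudyEffect:
    """The plate's vehicle aggregate (median across all vehicle wells)."""
    vehicles = [s for s in study_effects if s.role == "vehicle"]
    if not vehicles:
        raise NormalizationError("plate has no vehicle treatment")
    if len(vehicles) > 1:
        raise NormalizationError("plate has multiple vehicle treatments")
    return vehicles[0]


def apply_vehicle_correction(
    study_effects: Sequence[StudyEffect],
) -> list[StudyEffect]:
    """Fill ΔΔ% on every study effect using the plate's vehicle medians."""
    ref = vehicle_reference(study_effects)
    for s in study_effects:
        for param in PARAMETERS:
            med = s.delta_median.get(param)
            veh = ref.delta_median.get(param)
            if med is None or veh is None:
                s.dd[param] = None
            else:
                s.dd[param] = delta_delta(med, veh)
    return list(study_effects)


def apply_plate_qc(
    well_qc: Mapping[str, tuple[str, str | None]],
    study_effects: Sequence[StudyEffect],
    plate_id: str = "plate",
    config: QCConfig | None = None,
) -> PlateQCReport:
    """Plate-level acceptance: beat-rate outlier fraction and control responses.

    The plate fails when more than ``max_br_outlier_fraction`` of its wells
    violate the baseline beat-rate criteria (silent wells count — their rate
    is outside 30–90), or when any positive-control criterion whose
    compound/concentration is present on the plate is triggered.
    """
    config = config or QCConfig()
    exclusions = [(w, r) for w, (s, r) in sorted(well_qc.items()) if s == "excluded"]
    n_wells = len(well_qc)
    if n_wells == 0:
        raise ValueError("plate has no wells")
    n_br = sum(1 for _, r in exclusions if r in ("no_beating", "br_out_of_range"))
    frac = n_br / n_wells

    reasons: list[str] = []
    if frac > config.max_br_outlier_fraction:
        reasons.append("br_criteria")

    for crit in config.positive_controls:
        matches = [
            s
            for s in study_effects
            if s.role == "positive_control"
            and s.compound.lower() == crit.compound.lower()
            and math.isclose(s.concentration_um, crit.concentration_um, rel_tol=1e-6)
        ]
        for s in matches:
            if crit.triggered(s.dd.get(crit.parameter)):
                reasons.append(crit.reason)

    return PlateQCReport(
        plate_id=plate_id,
        n_wells=n_wells,
        well_exclusions=exclusions,
        br_outlier_fraction=frac,
        plate_pass=not reasons,
        plate_fail_reasons=reasons,
    )
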