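"""End-to-end plate analysis: features → QC → normalization → scoring."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .effects import (
    PlateQCReport,
    QCConfig,
    StudyEffect,
    WellEffect,
    aggregate_treatment,
    apply_plate_qc,
    apply_vehicle_correction,
    apply_well_qc,
    compute_well_effects,
)
from .features import FeatureConfig, WellSummary, summarize_well
from .plate import PlateDataset
from .scoring import HazardResult, ScoringMatrix, score_study

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one plate analysis produces."""

    plate_id: str
    qc_report: PlateQCReport
    well_summaries: dict[str, dict[str, WellSummary]] = field(default_factory=dict)
    well_effects: list[WellEffect] = field(default_factory=list)
    study_effects: list[StudyEffect] = field(default_factory=list)
    hazard_results: list[HazardResult] = field(default_factory=list)

    @property
    def plate_passed(self) -> bool:
        return self.qc_report.plate_pass


def run_pipeline(
    dataset: PlateDataset,
    matrix: ScoringMatrix | None = None,
    feature_config: FeatureConfig | None = None,
    qc_config: QCConfig | None = None,
    score_roles: tuple[str, ...] = ("test", "positive_control"),
) -> PipelineResult:
    """Analyze one plate dataset end to end.

    Runs feature extraction on every well and phase, applies well-level QC,
    computes Δ% effects and plate-median ΔΔ% per treatment, evaluates
    plate-level QC (beat-rate criteria and positive-control responses), and
    — only if the plate passes — scores every non-vehicle treatment against
    the scoring matrix.  A QC-failed plate returns its QC report and no
    hazard results.  The run is deterministic: identical inputs give
    identical outputs.
    """
    if matrix is None:
        from . import default_matrix

        matrix = default_matrix()
    feature_config = feature_config or FeatureConfig()
    qc_config = qc_config or QCConfig()

    summaries: dict[str, dict[str, WellSummary]] = {}
    for well in dataset.wells:
        try:
            summaries[well] = summarize_well(dataset.recordings[well], feature_config)
        except ValueError as exc:
            raise ValueError(f"feature extraction failed for well {well}: {exc}") from exc

    baseline_summaries = {w: s["baseline"] for w, s in summaries.items()}
    well_qc = apply_well_qc(baseline_summaries, dataset.annotations, qc_config)
    for well, (status, reason) in sorted(well_qc.items()):
        if status == "excluded":
            logger.info("plate %s: well %s excluded (%s)", dataset.plate_id, well, reason)

    well_effects = compute_well_effects(summaries, dataset.layout, well_qc)

    by_treatment: dict = {}
    for eff in well_effects:
        if eff.included:
            by_treatment.setdefault(eff.treatment, []).append(eff)
    study_effects: list[StudyEffect] = []
    for trt in sorted(by_treatment, key=lambda t: (t.role, t.compound, t.concentration_um)):
        study_effects.append(
            aggregate_treatment(by_treatment[trt], plate_id=dataset.plate_id, config=qc_config)
        )
    has_vehicle = any(s.role == "vehicle" for s in study_effects)
    if has_vehicle:
        apply_vehicle_correction(study_effects)

    qc_report = apply_plate_qc(well_qc, study_effects, dataset.plate_id, qc_config)
    for s in study_effects:
        s.qc_passed = qc_report.plate_pass

    hazard_results: list[HazardResult] = []
    if qc_report.plate_pass and has_vehicle:
        for s in study_effects:
            if s.role in score_roles:
                result = score_study(s, matrix)
                if result.override_applied:
                    logger.info(
                        "plate %s: %s@%g uM EAD override -> very_high",
                        dataset.plate_id, s.compound, s.concentration_um,
                    )
                hazard_results.append(result)
    elif not qc_report.plate_pass:
        logger.warning(
            "plate %s failed QC (%s); no hazard scores produced",
            dataset.plate_id, ", ".join(qc_report.plate_fail_reasons),
        )

    return PipelineResult(
        plate_id=dataset.plate_id,
        qc_report=qc_report,
        well_summaries=summaries,
        well_effects=well_effects,
        study_effects=study_effects,
        hazard_results=hazard_results,
    )
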