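"""cthazard: cardiac hazard scoring from calcium-transient screening.

Turns well-level calcium-fluorescence recordings of beating hiPSC-derived
cardiomyocytes into per-compound, per-concentration cardiac hazard labels
(no / low / high / very high) via beating-parameter extraction (CTD90, beat
rate, amplitude, arrest, EAD- and fibrillation-like events), vehicle-
normalized ΔΔ% effects, Wilks tolerance-interval cutoffs and a weighted
scoring matrix.  A seeded plate simulator makes the whole pipeline testable
without laboratory data.
"""

from __future__ import annotations

from importlib import resources

from .calibration import build_default_matrix, calibration_delta_samples, reference_models
from .effects import (
    PlateQCReport,
    PositiveControlCriterion,
    QCConfig,
    StudyEffect,
    WellEffect,
    aggregate_treatment,
    apply_plate_qc,
    apply_vehicle_correction,
    apply_well_qc,
    compute_well_effects,
    delta_delta,
    delta_percent,
)
from .features import (
    Beat,
    FeatureConfig,
    WellSummary,
    compute_ctd90,
    detect_beats,
    detect_eads,
    detect_fibrillation,
    summarize_well,
)
from .io import read_plate, write_plate
from .pipeline import PipelineResult, run_pipeline
from .plate import PlateDataset, TraceRecording, Treatment, well_ids_96
from .scoring import (
    HazardResult,
    LabelRange,
    ScoringMatrix,
    rank_compounds,
    score_incidence,
    score_parameter,
    score_study,
)
from .simulate import (
    BaselineDistributions,
    DrugEffectModel,
    EffectCurve,
    EventFlags,
    PlateSimConfig,
    ProbCurve,
    TransientShape,
    apply_drug_model,
    control_plate_layout,
    generate_plate,
    generate_trace,
    vehicle_layout,
)
from .tolerance import (
    CutoffSet,
    DirectionCutoffs,
    ToleranceInterval,
    derive_cutoffs,
    min_sample_size,
    wilks_ti,
)

__version__ = "0.1.0"


def default_matrix() -> ScoringMatrix:
    """The packaged default scoring matrix (synthetic calibration)."""
    ref = resources.files("cthazard").joinpath("data/default_matrix.yaml")
    with resources.as_file(ref) as path:
        return ScoringMatrix.load(path)
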