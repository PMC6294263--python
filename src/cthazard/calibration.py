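"""Synthetic calibration of the default scoring matrix.

The numeric cutoffs of a scoring matrix are assay-specific configuration:
they come from tolerance intervals of vehicle and control-drug Δ% effects
measured in the laboratory.  This package ships a default matrix calibrated
on a synthetic reference set instead: seeded draws of per-well Δ% effects
for vehicle and for five pharmacological control classes of the simulator
(hERG-blocker-like CTD90 prolongation, K_ATP-opener-like shortening,
beta-agonist-like BR/Amp increase, funny-current-blocker-like BR decrease,
and calcium-antagonist-like Amp suppression), each at a reference
concentration.  The resulting cutoffs are therefore properties of the
simulator's study conditions, not of any laboratory dataset.

Samples are drawn at the shape level (drug curves plus the generator's
vehicle drift), which is what plate-median Δ% values estimate; the full
trace-level pipeline reproduces them within measurement error.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .scoring import ScoringMatrix, default_weights
from .simulate import (
    BaselineDistributions,
    DrugEffectModel,
    EffectCurve,
    ProbCurve,
    apply_drug_model,
)
from .tolerance import CutoffSet, derive_cutoffs

__all__ = [
    "reference_models",
    "calibration_delta_samples",
    "build_default_matrix",
    "DEFAULT_MATRIX_SEED",
]

# Frozen seed of the packaged default matrix (data/default_matrix.yaml).
DEFAULT_MATRIX_SEED = 20181211


def reference_models() -> dict[str, DrugEffectModel]:
    """Synthetic analogues of the assay's control/reference drug classes.

    Emax values are fractional changes of the affected parameter; ec50 in
    μM.  The names mirror the pharmacological role each model emulates; the
    plate-acceptance controls (dofetilide / isoprenaline / nimodipine) map
    onto the first, third and fifth models.
    """
    return {
        # I_Kr (hERG) blocker: strong CTD90 prolongation, EADs at high exposure
        "herg_blocker": DrugEffectModel(
            ctd90=EffectCurve(emax=0.8, ec50_um=0.006),
            ead=ProbCurve(pmax=0.85, ec50_um=0.05),
        ),
        # K_ATP opener: CTD90 shortening
        "katp_opener": DrugEffectModel(ctd90=EffectCurve(emax=-0.5, ec50_um=0.05)),
        # beta-adrenergic agonist: BR and Amp increase, mild CTD90 shortening
        "beta_agonist": DrugEffectModel(
            br=EffectCurve(emax=0.8, ec50_um=0.03),
            amp=EffectCurve(emax=0.5, ec50_um=0.03),
        ),
        # funny-current blocker: selective BR decrease
        "funny_blocker": DrugEffectModel(br=EffectCurve(emax=-0.5, ec50_um=0.1)),
        # calcium-channel antagonist: strong Amp suppression, CTD90 shortening,
        # BR increase (the class's signature in hiPSC-CM monolayers)
        "ca_antagonist": DrugEffectModel(
            amp=EffectCurve(emax=-0.8, ec50_um=0.05),
            ctd90=EffectCurve(emax=-0.25, ec50_um=0.02),
            br=EffectCurve(emax=0.3, ec50_um=0.05),
        ),
    }


# control class -> (reference concentration μM, parameter, direction of action)
_CALIBRATION_PLAN: tuple[tuple[str, float, str, str], ...] = (
    ("herg_blocker", 0.006, "ctd90", "up"),
    ("katp_opener", 0.05, "ctd90", "down"),
    ("beta_agonist", 0.03, "br", "up"),
    ("beta_agonist", 0.03, "amp", "up"),
    ("funny_blocker", 0.1, "br", "down"),
    ("ca_antagonist", 0.05, "amp", "down"),
)


def calibration_delta_samples(
    seed: int = DEFAULT_MATRIX_SEED,
    n_per_group: int = 100,
    drift_sd_pct: float = 3.0,
    baseline: BaselineDistributions | None = None,
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], np.ndarray]]:
    """Seeded vehicle and control Δ% samples for cutoff derivation.

    Returns ``(vehicle_samples, control_samples)`` in the shapes
    ``derive_cutoffs`` expects.  Vehicle Δ% is the generator's drift
    (normal, sd ``drift_sd_pct`` percentage points).  Control Δ% combines
    the drug model's fractional effect at its reference concentration —
    evaluated well by well on shapes drawn from the baseline heterogeneity
    distributions — with the same drift.
    """
    baseline = baseline or BaselineDistributions()
    models = reference_models()
    ss = np.random.SeedSequence(seed)
    s_vehicle, s_controls = ss.spawn(2)

    rng_v = np.random.default_rng(s_vehicle)
    vehicle = {
        param: rng_v.normal(0.0, drift_sd_pct, n_per_group)
        for param in ("ctd90", "br", "amp")
    }

    controls: dict[tuple[str, str], np.ndarray] = {}
    model_names = sorted({p[0] for p in _CALIBRATION_PLAN})
    child = dict(zip(model_names, s_controls.spawn(len(model_names))))
    effects_cache: dict[str, np.ndarray] = {}
    for model_name in model_names:
        conc = next(c for m, c, _, _ in _CALIBRATION_PLAN if m == model_name)
        rng = np.random.default_rng(child[model_name])
        rows = []
        for i in range(n_per_group):
            shape = baseline.draw_shape(rng)
            perturbed, _ = apply_drug_model(shape, models[model_name], conc, seed=int(rng.integers(2**31)))
            d_ctd = 100.0 * (perturbed.implied_ctd90_ms / shape.implied_ctd90_ms - 1.0)
            d_br = 100.0 * (perturbed.implied_beat_rate / shape.implied_beat_rate - 1.0)
            d_amp = 100.0 * (perturbed.amplitude / shape.amplitude - 1.0)
            drift = rng.normal(0.0, drift_sd_pct, 3)
            rows.append([d_ctd + drift[0], d_br + drift[1], d_amp + drift[2]])
        effects_cache[model_name] = np.asarray(rows)

    param_col = {"ctd90": 0, "br": 1, "amp": 2}
    for model_name, _conc, param, direction in _CALIBRATION_PLAN:
        controls[(param, direction)] = effects_cache[model_name][:, param_col[param]]
    return vehicle, controls


def build_default_matrix(
    seed: int = DEFAULT_MATRIX_SEED,
    n_per_group: int = 100,
    weights: Mapping[str, Mapping[str, int]] | None = None,
    coverage_p: float = 0.90,
    confidence_gamma: float = 0.95,
) -> ScoringMatrix:
    """Derive the default scoring matrix from the synthetic calibration set."""
    vehicle, controls = calibration_delta_samples(seed=seed, n_per_group=n_per_group)
    cutoffs: CutoffSet = derive_cutoffs(
        vehicle, controls, coverage_p=coverage_p, confidence_gamma=confidence_gamma
    )
    return ScoringMatrix.from_cutoffs(cutoffs, weights=weights or default_weights())
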