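"""Simulator contracts: waveform morphology, determinism, drug models, plates."""

from __future__ import annotations

import numpy as np
import pytest

from cthazard.features import detect_beats, summarize_well
from cthazard.simulate import (
    BaselineDistributions,
    DrugEffectModel,
    EffectCurve,
    PlateSimConfig,
    ProbCurve,
    TransientShape,
    apply_drug_model,
    generate_plate,
    generate_trace,
    vehicle_layout,
)
from cthazard.plate import Treatment
from cthazard.effects import apply_well_qc

from conftest import analytic_ctd90_ms


class TestGenerateTrace:
    def test_one_hz_train_has_sixty_peaks_per_minute(self):
        shape = TransientShape(period_ms=1000.0, noise_sd=2.0)
        trace = generate_trace(shape, 60.0, 66.7, seed=3)
        beats = detect_beats(trace)
        assert abs(len(beats) - 60) <= 1

    def test_equal_seeds_give_identical_samples(self):
        shape = TransientShape(noise_sd=5.0)
        a = generate_trace(shape, 60.0, 66.7, seed=11)
        b = generate_trace(shape, 60.0, 66.7, seed=11)
        assert np.array_equal(a.samples, b.samples)
        c = generate_trace(shape, 60.0, 66.7, seed=12)
        assert not np.array_equal(a.samples, c.samples)

    def test_noise_free_ctd90_recovered_from_trace(self, clean_shape):
        # decay constant 200 ms -> isolated-kernel CTD90 of 200*ln10 ≈ 460.5 ms;
        # the window median absorbs per-beat sampling-phase jitter
        from cthazard.features import compute_ctd90

        trace = generate_trace(clean_shape, 76.0, 66.7, seed=0)
        beats = detect_beats(trace)
        vals = [
            compute_ctd90(trace, beats[i], next_upstroke_index=beats[i + 1].upstroke_index)
            for i in range(len(beats) - 1)
        ]
        tol_ms = 1.5 * 1000.0 / 66.7
        assert np.median(vals) == pytest.approx(200.0 * np.log(10.0), abs=tol_ms)

    @pytest.mark.parametrize("duration, rate", [(0.0, 66.7), (30.0, 66.7), (60.0, 0.0), (-5.0, 66.7)])
    def test_invalid_duration_or_rate_rejected(self, duration, rate):
        with pytest.raises(ValueError):
            generate_trace(TransientShape(), duration, rate)


class TestApplyDrugModel:
    def test_zero_concentration_is_identity(self):
        shape = TransientShape()
        model = DrugEffectModel(
            ctd90=EffectCurve(0.6, 1.0), ead=ProbCurve(1.0, 0.0), arrest=ProbCurve(1.0, 0.0)
        )
        out, flags = apply_drug_model(shape, model, 0.0, seed=5)
        assert out == shape
        assert not flags.any()

    def test_half_maximal_effect_at_midpoint(self):
        shape = TransientShape()
        model = DrugEffectModel(ctd90=EffectCurve(emax=0.6, ec50_um=1.0))
        out, _ = apply_drug_model(shape, model, 1.0, seed=0)
        assert out.implied_ctd90_ms == pytest.approx(shape.implied_ctd90_ms * 1.30, rel=1e-9)

    def test_certain_ead_probability_always_flags(self):
        shape = TransientShape()
        model = DrugEffectModel(ead=ProbCurve(pmax=1.0, ec50_um=0.0))
        for seed in range(25):
            _, flags = apply_drug_model(shape, model, 0.5, seed=seed)
            assert flags.ead

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            apply_drug_model(TransientShape(), DrugEffectModel(), -1.0, seed=0)

    def test_effect_curves_monotone_in_concentration(self):
        curve = EffectCurve(emax=0.8, ec50_um=0.1)
        effects = [curve.effect(c) for c in (0.0, 0.01, 0.1, 1.0, 10.0)]
        assert effects == sorted(effects)
        prob = ProbCurve(pmax=0.7, ec50_um=0.5)
        probs = [prob.prob(c) for c in (0.0, 0.1, 1.0, 10.0)]
        assert probs == sorted(probs) and all(0 <= p <= 1 for p in probs)


class TestGeneratePlate:
    fast = PlateSimConfig(duration_baseline_s=65.0, duration_post_s=65.0,
                          phases=("baseline", "post30"))

    def test_single_well_layout_has_all_configured_phases(self):
        layout = {"A01": Treatment("vehicle", 0.0, "vehicle")}
        ds = generate_plate(layout, seed=1, config=PlateSimConfig(
            duration_baseline_s=65.0, duration_post_s=65.0))
        assert set(ds.recordings["A01"]) == {"baseline", "post15", "post30"}

    def test_duplicate_well_in_layout_rejected(self):
        pairs = [
            ("A01", Treatment("vehicle", 0.0, "vehicle")),
            ("A01", Treatment("vehicle", 0.0, "vehicle")),
        ]
        with pytest.raises(ValueError, match="more than once"):
            generate_plate(pairs, seed=1)

    def test_missing_model_for_treated_compound_rejected(self):
        layout = {"A01": Treatment("drugX", 1.0, "test")}
        with pytest.raises(ValueError, match="drugX"):
            generate_plate(layout, seed=1)

    def test_determinism_byte_for_byte_after_serialization(self, tmp_path):
        from cthazard.io import write_plate

        layout = dict(list(vehicle_layout().items())[:4])
        digests = []
        for run in ("a", "b"):
            ds = generate_plate(layout, seed=42, config=self.fast)
            out = write_plate(ds, tmp_path / run)
            import hashlib

            h = hashlib.sha256()
            for f in sorted(out.iterdir()):
                h.update(f.name.encode() + f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_vehicle_plates_mostly_pass_well_qc(self):
        # Monte-Carlo over >= 20 seeds: at least 90% of wells on an
        # all-vehicle 96-well plate pass baseline QC
        total = passed = 0
        for seed in range(20):
            ds = generate_plate(vehicle_layout(), seed=seed, config=self.fast)
            summaries = {
                w: summarize_well(ds.recordings[w])["baseline"] for w in ds.wells
            }
            qc = apply_well_qc(summaries, ds.annotations)
            total += len(qc)
            passed += sum(1 for s, _ in qc.values() if s == "included")
        assert passed / total >= 0.90

    def test_prolongation_shifts_treated_delta_above_vehicle(self):
        # strong-prolongation model at top concentration: treated wells'
        # Δ% CTD90 median exceeds the vehicle median in >=95% of seeded plates
        from cthazard.pipeline import run_pipeline

        model = DrugEffectModel(ctd90=EffectCurve(emax=0.6, ec50_um=0.05))
        layout = {}
        from cthazard.plate import well_ids_96

        ids = well_ids_96()
        for w in ids[:8]:
            layout[w] = Treatment("vehicle", 0.0, "vehicle")
        for w in ids[8:16]:
            layout[w] = Treatment("prolonger", 5.0, "test")

        wins = 0
        n_plates = 100
        for seed in range(n_plates):
            ds = generate_plate(layout, models={"prolonger": model}, seed=seed, config=self.fast)
            res = run_pipeline(ds)
            drug = next(s for s in res.study_effects if s.compound == "prolonger")
            veh = next(s for s in res.study_effects if s.role == "vehicle")
            if (
                drug.delta_median["ctd90"] is not None
                and drug.delta_median["ctd90"] > veh.delta_median["ctd90"]
            ):
                wins += 1
        assert wins / n_plates >= 0.95


class TestBaselineHeterogeneity:
    def test_drawn_shapes_span_physiologic_ranges(self, rng):
        dist = BaselineDistributions()
        shapes = [dist.draw_shape(rng) for _ in range(500)]
        brs = np.array([s.implied_beat_rate for s in shapes])
        ctds = np.array([s.implied_ctd90_ms for s in shapes])
        assert brs.min() >= 20.0 and brs.max() <= 110.0
        assert np.mean((brs >= 30) & (brs <= 90)) >= 0.95
        assert np.all(ctds < np.array([s.period_ms for s in shapes]))

    def test_invariant_ctd90_shorter_than_period(self):
        with pytest.raises(ValueError):
            TransientShape(period_ms=-1.0)
        s = TransientShape.from_ctd90(400.0, 60.0)
        assert s.implied_ctd90_ms == pytest.approx(400.0)
        assert s.implied_ctd90_ms < s.period_ms


class TestAnalyticOracleAgreement:
    def test_isolated_kernel_matches_continuous_oracle(self, clean_shape):
        # the closed-form isolated-kernel CTD90 agrees with the independent
        # continuous-waveform oracle when transients are well separated
        assert analytic_ctd90_ms(clean_shape) == pytest.approx(
            clean_shape.implied_ctd90_ms, abs=2.0
        )
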