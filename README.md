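# cthazard

Cardiac hazard scoring from calcium-transient screening of human iPSC-derived
cardiomyocytes (hiPSC-CMs).

Spontaneously beating hiPSC-CM monolayers, loaded with a calcium-sensitive
dye, report drug effects on cardiac electrophysiology through their
whole-well fluorescence signal.  `cthazard` turns such well-level recordings
into a per-compound, per-concentration **cardiac hazard label** — *no*
(green), *low* (yellow), *high* (red) or *very high* (black) — the kind of
call an early safety-pharmacology screen needs to rank drug candidates
before committing to ex vivo or in vivo follow-up.

## The method

For every well, three beating parameters are extracted from each recording
(a pre-compound baseline and post-compound recordings around 15 and 30 min),
as medians over all beats in a one-minute analysis window:

- **CTD90** — calcium-transient duration at 90% of decay after the peak
  (a surrogate for action-potential/QT duration),
- **BR** — beat rate (transients per minute),
- **Amp** — transient amplitude (peak minus local baseline),

plus abnormal-phenotype flags: **beat stop** (BR < 5/min at 30 min),
**EAD-like events** (extra calcium spikes during a transient's decay, the
assay's torsadogenic surrogate), and **fibrillation-like activity**
(sustained fast, low-amplitude transients).

Effects are normalized per well and plate:

```
Δ%  = 100 · (x₃₀ − x₀) / x₀                 (30 min vs baseline, per well)
ΔΔ% = median Δ%(drug) − median Δ%(vehicle)  (per plate treatment, n = 4–8)
```

Cutoffs between *no effect*, *mild* and *strong* ΔΔ% zones come from
nonparametric **Wilks tolerance intervals** (sample min–max, 95% confidence
to cover 90% of the population; the inter-extreme coverage is
Beta(n−1, 2)-distributed): the vehicle interval, re-centred at zero, bounds
the no-effect zone, and control-drug intervals, corrected for the vehicle
offset, anchor the strong cutoffs.  Each study's zone hits are converted to
weighted points, summed with beat-stop incidence-zone and fibrillation
points, and the total maps to a label.  Any EAD-positive study is
categorized as *very high* hazard regardless of its numeric score.

Quality control mirrors screening practice: wells silent, non-synchronous
or outside 30–90 beats/min at baseline are excluded; plates with more than
10% of wells violating the beat-rate band, or with an insensitive positive
control (hERG blocker, beta-agonist, calcium antagonist), are rejected
whole.

Because raw screening data are proprietary, the package includes a seeded
**plate simulator** (waveform-level: logistic upstroke, exponential decay,
heterogeneous wells, vehicle drift, saturating concentration–effect curves,
EAD/fibrillation/arrest synthesis) so the entire pipeline is testable and
demonstrable end to end.  The shipped default scoring matrix is calibrated
on this synthetic reference set — it is configuration, not a laboratory
result.

## Worked example

Simulate a plate carrying vehicle, the three positive controls and a
hERG-blocker-like test series, then score it:

```bash
cthazard simulate --seed 7 --out demo_plate --preset demo --duration 75 --wells 44
cthazard score --plate demo_plate --out demo_results
```

which prints the concentration-dependent hazard table:

```
    compound  concentration_um  total_score     label  color  override_applied
       CPD-1             0.001            1       low yellow             False
       CPD-1             0.003            1 very_high  black              True
       CPD-1             0.010            1 very_high  black              True
       CPD-1             0.030            3 very_high  black              True
isoprenaline             0.100            5      high    red             False
  nimodipine             0.100            4      high    red             False
  dofetilide             0.003            1       low yellow             False
```

Reading it: the simulated hERG blocker CPD-1 leaves vehicle variability at
1 nM (one *low* point for mild CTD90 prolongation), and from 3 nM on
triggers EAD-like events in at least one well, so the override labels those
studies *very high* (black) irrespective of the summed score — at 30 nM the
CTD90 prolongation alone has also reached the strong zone (3 points).  The
beta-agonist and calcium-antagonist controls land *high* through their
strong BR/Amp signatures, and the hERG-blocker control at its low QC
concentration shows the expected mild prolongation (*low*).  `demo_results/`
contains the table (`hazard.csv`), per-study ΔΔ% effects
(`study_effects.csv`), the full point breakdown (`hazard.json`) and the QC
report (`qc.json`).

Library use mirrors the CLI: `generate_plate(...)` →
`run_pipeline(dataset)` → `rank_compounds(result.hazard_results)`; cutoff
derivation is `derive_cutoffs(vehicle_samples, control_samples)` and
matrices round-trip through YAML via `ScoringMatrix.save/load`.

## Layout

```
src/cthazard/
  simulate.py     seeded plate/trace simulator and drug-effect models
  features.py     beat detection, CTD90/BR/Amp, EAD & fibrillation detectors
  effects.py      Δ%/ΔΔ% normalization, well and plate QC
  tolerance.py    Wilks tolerance intervals, cutoff derivation
  scoring.py      scoring matrix, hazard labels, ranking
  calibration.py  synthetic reference set behind the default matrix
  io.py, cli.py, pipeline.py
  data/default_matrix.yaml
docs/methods.md   model, parameters, design choices, limitations
```
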