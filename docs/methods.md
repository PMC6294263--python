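# Methods

This note documents the models, parameters and design choices behind
`cthazard`: what each stage assumes, which knobs matter, what the synthetic
data emulate (and do not), and where the numerically delicate spots are.

## 1. Signal model and feature extraction

A well's recording is modelled as a baseline fluorescence level plus a sum
of per-beat transient kernels and additive Gaussian noise.  Each kernel has
a logistic upstroke spanning eight upstroke time constants (rescaled to
rise exactly from 0 to 1) followed by a single-exponential decay.  Under
this kernel the transient duration at 90% decay, measured from the upward
10%-amplitude crossing, has the closed form

    CTD90 = 6.0466 · τ_up + τ_decay · ln 10,

which anchors the feature-recovery tests.  On a periodic waveform the
operational value differs slightly (the decay rides on the previous beat's
tail); the test oracle therefore evaluates the continuous steady-state
waveform on a fine grid and applies the same 10%/90% definition.

Beat detection uses local maxima (scipy `find_peaks`) with a prominence
threshold of max(0.55 × robust trace range, 10 × estimated sample noise)
and a 300 ms refractory distance.  The two-part threshold keeps flat noisy
traces beat-free while rejecting EAD-like secondary spikes (≤ ~0.5 of the
beat amplitude) as primary beats.  A final beat whose decay is cut off by
the end of the recording is recovered from its upstroke, since symmetric
prominence would otherwise discard it.  Parameter summaries are medians
over all beats whose peak falls in the analysis window — the **final 60 s**
of each recording, a choice made because the assay protocol specifies a
one-minute interval without a position.  Beat rate is the beat count in
that window (transients per minute), which is exact on noise-free input and
carries ±1-count quantization on real input.

CTD90 per beat runs from the interpolated 10%-amplitude rise crossing to
the first interpolated post-peak return to baseline + 10% of amplitude;
linear interpolation gives sub-sample resolution at 66.7 Hz.  A beat whose
decay never reaches that level before the next beat's upstroke has no CTD90
and is excluded from the median (counted in `n_ctd90_undefined`).

EAD-like events are secondary maxima between a beat's peak and the next
upstroke with prominence above 0.15 × that beat's amplitude, occurring
before the decay completes.  The threshold is configuration: in the
laboratory these events are assessed by eye, and automation needs an
explicit rule; 0.15 sits well above the noise floor (≈ 0.008 of amplitude
at default settings) and well below the smallest synthesized spike (0.25).

Fibrillation-like activity is a sustained stretch (≥ 20 s of consecutive
5-s windows) whose local rate is ≥ 3× the well's baseline rate while local
amplitude is ≤ 0.3× the baseline amplitude.  All three constants are
configurable; they operationalize a qualitative phenotype description.
A flat (arrested) trace has no peaks and is classified as beat stop, never
fibrillation.  Beat stop itself is strict: BR < 5/min in the 30-min
recording; a well silent at 15 min that beats again at 30 min is not
arrested.

## 2. Normalization and quality control

Per-well effects are Δ% = 100·(x₃₀ − x₀)/x₀; wells that arrest carry no
parameter Δ% (arrest is an incidence, not a −100% change — scoring it both
ways would double-count).  Treatment aggregation is the median over a
plate's included, still-beating wells (a warning is logged outside the
expected 4–8 wells); ΔΔ% subtracts the same plate's vehicle median, with
the vehicle reference taken across all included vehicle wells of the plate.

Well QC excludes silent wells, wells annotated non-synchronous (desynchrony
is not inferable from a single integrated whole-well trace, so it enters as
an upstream annotation), and wells with baseline BR strictly below 30 or
strictly above 90 beats/min — the bounds themselves pass.  Plate QC rejects
plates with more than 10% of wells violating the BR criteria (silent wells
count: their rate is outside the band) and plates whose positive controls
under-respond: CTD90 ΔΔ% < 15 for the hERG blocker at 3 nM, BR ΔΔ% < 30
for the beta-agonist at 0.1 μM, or CTD90 ΔΔ% > −10 for the calcium
antagonist at 0.1 μM.  Criteria apply only to controls actually present.

## 3. Tolerance intervals and cutoffs

The two-sided Wilks interval is the sample (min, max); its population
coverage is Beta(n−1, 2)-distributed regardless of the sampled law, so the
achieved confidence for coverage ≥ p is the Beta upper tail at p.  At
p = 0.90, γ = 0.95 the minimum adequate sample is n = 46; smaller samples
return a flagged interval rather than an error, so pilot plates remain
analyzable with a warning.

`derive_cutoffs` re-centres the vehicle interval at zero (both bounds minus
the interval midpoint) to bound the no-effect zone, and anchors each strong
cutoff at the control interval's bound on the far side of its direction of
action, minus the vehicle midpoint.  A control whose strong bound falls
inside the no-effect zone is rejected as too weak.  A mild reference bound
defaults to the midpoint between the no-effect and strong bounds and may be
supplied explicitly; the scoring zones themselves are delimited by the
no-effect and strong bounds (values exactly on a boundary take the milder
zone — conservative toward fewer false positives).

## 4. Scoring matrix and labels

Default weights: CTD90 mild 1 / strong 3 in both directions; BR and Amp
mild 1 / strong 2.  Beat-stop incidence has three zones — (0, 0.5] → 1,
(0.5, 1) → 2, exactly 1.0 → 4 — because partial arrest occurs with
relatively benign sodium-channel blockers while complete arrest is a strong
signal on its own.  Any fibrillation incidence adds 4 points.  Totals map
to labels 0 → no, 1–2 → low, ≥ 3 → high; complete arrest or fibrillation
alone therefore reaches *high*.  EAD incidence > 0 overrides the label to
*very high*; the label is reachable no other way, making it a biconditional
with the EAD observation.  All numbers are configuration (YAML round-trip,
structurally validated); negative points are not used by the default matrix
but are not forbidden by the format.

The shipped `data/default_matrix.yaml` is produced by
`calibration.build_default_matrix()` at a frozen seed: vehicle Δ% is the
generator's drift (normal, sd 3 percentage points, n = 100 per parameter)
and five control classes (hERG-blocker-, K_ATP-opener-, beta-agonist-,
funny-current-blocker- and calcium-antagonist-like models at reference
concentrations) supply the directional strong anchors.  A test regenerates
the matrix from the seed and asserts equality with the shipped file.

## 5. The simulator: what it emulates and what it does not

Defaults follow the assay's stated conditions: 66.7 Hz sampling, 96-well
plates, three phases, spontaneous rates mostly within 30–90 beats/min
(truncated normal, mean 60, sd 12, bounds 20–110), CTD90 normal (mean
500 ms, sd 80 ms, kept within 85% of the cycle), vehicle drift of sd 3
percentage points per parameter (the assay reports low vehicle variability
without a number; the spread is exposed in configuration).  Drug action is
a saturating curve per parameter (fractional emax, EC50) plus
concentration-dependent Bernoulli events for EAD, fibrillation and arrest.
A transient that would outgrow 80% of the cycle delays the next spontaneous
beat instead of being truncated — over-prolongation therefore slows the
rate, as hERG block does at high exposure, and the measured dose-response
stays monotone.  Randomness derives from one master seed via per-well
`SeedSequence` spawns keyed by sorted well id, so datasets are byte-stable
under serialization regardless of iteration order.

Recording durations default to the protocol's 3-min baseline and 5-min
post recordings; because analysis uses only the final minute, the test
suite and examples shorten phases to 65–76 s, which changes no derived
statistic.  Heavier checks use 50–100 seeded plates of 32–96 wells.

Not emulated: dye kinetics and photobleaching, optical crosstalk,
batch-to-batch hiPSC-CM maturity differences, non-synchronous beating
waveforms (only the annotation), rate-dependent CTD90 correction
(uncorrected values are used throughout), and torsade-de-pointes
probability beyond the EAD override.  Passing tests therefore demonstrate
the pipeline's correctness and calibration under these idealized
conditions, not performance on laboratory recordings.

## 6. Numerical notes and limitations

- At 66.7 Hz a single beat's CTD90 carries up to ~1 sample period of
  sampling-phase error (fast upstrokes make the rise interpolation coarse);
  the per-window median absorbs this, and accuracy contracts are stated on
  medians.
- Beat-count beat rate is quantized to 1/min; Δ% BR inherits ~1.7%
  granularity at 60 beats/min, small against the ±10 ΔΔ% no-effect band.
- Heavily overlapping transients (CTD90 approaching the cycle length) bias
  the measured CTD90 downward via the elevated inter-beat baseline; the
  simulator's refractoriness rule keeps synthetic data out of the worst of
  this regime, but real pathological traces will show it.
- The EAD override treats a single EAD-positive well as decisive; with
  4–8 wells per study this is deliberately sensitive (the screening
  posture) and will overcall relative to clinical torsade incidence.
- Labels near zone boundaries are unstable under resampling by
  construction — a static-cutoff system shares this property with the
  laboratory original; the ranking, not single labels, is the robust
  output.
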