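# Methods

This note records the models, parameter choices and numerical rules behind
`bccancel`, and what the synthetic experiments do and do not demonstrate.

## Synthetic head model

The transfer functions from the bone transducer (BT) to the two cochleae
are phenomenological: the package's purpose is to test the *measurement
and analysis chain*, not skull mechanics, so the model encodes the
qualitative structure the psychoacoustic literature reports rather than a
biomechanical simulation.

**Frequency grid.** 250–8000 Hz; the default 50 Hz step gives the 156
measurement points of the fine-grid experiment.  Any step dividing the
span is accepted.

**Inter-cochlear phase difference (ICPD) skeleton.**  Ipsi-minus-contra
phase is built monotone increasing from three non-decreasing terms:

- a 180° offset with a shallow slope (4–12 °/kHz) below ~1 kHz — in the
  skull's mass-spring region the two temporal bones move approximately in
  antiphase, and the model asserts at construction that ipsi and contra
  phase differ by 180° ± 30° everywhere below 1 kHz;
- a smoothstep accumulation of 500–750° between 1 and 4 kHz (steep phase
  build-up where skull wave motion takes over);
- a constant 120–200 °/kHz slope above 4 kHz (wave propagation:
  approximately linear phase growth).

The ipsilateral path itself is a plain propagation delay of 0.25–0.40 ms
plus a gentle random level trend; the contralateral path is the
ipsilateral minus the ICPD skeleton.  All phases are stored continuously
(unwrapped); only the simulated measurement reduces them modulo 360, so
ground truth remains unambiguous for recovery scoring.

**Inter-cochlear level difference (ICLD).**  Small or slightly negative
(−3–0 dB) at low frequencies, rising by 12–16 dB via a smoothstep centred
mid-band (transcranial attenuation grows with frequency), with a 1–3 dB
fall-off above 6 kHz.  Positive ICLD means the ipsilateral cochlea
receives more.

**Anti-resonance notches.**  One per side, centre 1.5–3.8 kHz, width
280–400 Hz, depth 12–16 dB, realized as the ratio of a high-Q complex
zero to a moderate-Q pole at the same centre.  This couples the level dip
with the rapid local phase rotation that destructive interference of
multiple pathways physically implies.  The phase contribution is computed
with `atan2` on strictly-positive imaginary parts, so it is continuous in
frequency by construction; with the default widths the per-50 Hz phase
step stays well below the 180° aliasing limit of the unwrapping rule.

**Air-conduction paths.**  Flat, 0 dB / 0° and identical left/right by
default.  The ear subtraction attributes all asymmetry to the bone paths,
which is exact only for matched earphones; an optional mismatch parameter
(`ac_mismatch_db/_deg`) exists for sensitivity exploration, but no
measurement can separate AC-path from BC-path asymmetry, so it defaults
off and no magnitude is claimed for it.

**Session coupling jitter.**  Each sitting draws a gain offset (default
SD 1.5 dB) and a phase offset (default SD 15°) applied *identically* to
both bone paths — a coupling change at the transducer alters the drive
into the skull, hence both paths equally — plus a contralateral-only
phase ramp with slope SD 8 °/kHz.  The common-mode defaults produce raw
between-sitting discontinuities of a few dB / tens of degrees, as seen in
repeated-placement measurements; the contra-specific slope encodes the
greater placement sensitivity of the cross-skull path and grows linearly
with frequency.  The slope magnitude was set by a power analysis: with 8
sittings the sampling noise of a sample SD is ~27 %, and 8 °/kHz makes
the paired ipsi/contra SD comparison detectable at the strength human
studies report for this effect.  Perturbations with zero contra-specific
jitter leave the true inter-cochlear differences bit-identical — the
invariance the analysis stage relies on.

## Virtual participant

Human "free scrolling" is modelled as exhaustive search over the
quantized setting grid — 0.2 dB level steps, 2° phase steps, the scroll
resolutions of the procedure — with additive perceptual noise drawn once
per adjustment; no staircase is imposed because the procedure imposes
none.  Level matching maximises beat depth (min/max envelope ratio of
the 1-Hz-detuned pair, maximal iff the cochlear levels match); phase
nulling minimises the residual phasor magnitude; ties resolve to the
lower level / earlier grid phase.  One trial runs
ipsi-level → ipsi-phase → contra-level → contra-phase followed by two
further refinement iterations (configurable).  Insert earphones are
treated as perfectly isolating, so the two ears decouple and the
contralateral stage is independent of the ipsilateral canceller playing;
the ears are also treated as perceptually independent at low frequencies,
where in reality near-antiphase beats at the two ears make the task
harder — that difficulty is absorbed into the noise model below.

**Perceptual noise.**  Base SDs 0.4 dB and 4° at mid frequencies, scaled
by a frequency-dependent multiplier: equal to 5 at and below 1 kHz,
decaying exponentially above it with a 2.5 kHz constant, plus a 0.3/kHz
rise above 7 kHz.  The shape is a deliberate calibration: it reproduces
the reported difficulty pattern (grades worst at 1 kHz, improving to
~7 kHz, slightly worse again at 8 kHz) without modelling lateralization
perception.  The multiplier applies at 1 kHz inclusively because 1 kHz is
the lowest frequency of the repeated-measures experiment and is where the
grade minimum must sit.

**Grading.**  The listener's 1–5 rating is mapped from the achieved
residual attenuation 20·log10(before/after) through thresholds
(3, 12, 25, 40) dB for grades 2–5.  The verbal scale fixes only the
endpoints ("as loud as the start" / "nothing audible"); the interior
thresholds are an artifact decision, configurable.  Both ears receive the
grade of the worse ear, and grade-1 trials are excluded for both ears
together, since a poorly cancelled ipsilateral tone corrupts the
contralateral adjustment.

## Analysis rules

- **Within-sitting unwrapping**: nearest-360-multiple continuity at 50 Hz
  spacing; an exact 180° tie resolves toward the smaller absolute
  unwrapped value.  True steps above 180° per grid point would alias —
  with the default model the largest true step is under 100°.
- **Cross-sitting stitching**: the whole later band is shifted by the 360
  multiple minimising the step between the nearest retained frequencies
  on either side of the boundary (ties toward zero shift).  If the
  nominal boundary frequency was excluded, the nearest retained one is
  used and the output flagged.  The stitched series is offset so the
  anchor (lowest tested frequency, 250 Hz) lies in [0, 360); absolute
  values stay meaningless because they include per-sitting coupling.
- **Profiles**: ICPD/ICLD are plain ipsi-minus-contra differences on the
  common retained frequency set (intersection, with a warning, if the
  ears differ).
- **Variability**: per frequency × ear, sample SD (n−1) over sittings;
  phases are first shifted onto the 360° branch nearest the cell's
  circular mean, so a linear SD is meaningful for spreads ≪ 360°.
  Cells with fewer than 2 sittings are flagged and dropped from tests.
- **Paired t-test**: t = mean(d)/(sd(d)/√n) with the two-sided Student
  CDF; zero-variance differences are flagged degenerate (p = 1 if the
  mean difference is 0, else p = 0).  No multiple-testing correction is
  applied; p-values are reported raw.

## Canceller

Per-frequency design only: w = −H[source][off] / H[aux][off] gives
matched level and opposite phase at the off-target cochlea; no broadband
FIR synthesis.  Frequencies where the auxiliary path magnitude falls
below tolerance are marked infeasible.  The cancelling signal's own
contribution to the near cochlea is compensated only by the optional
exact 2×2 solve (`design_exact_drives`); the first-order design matches
the way the measurement itself is described.  The second transducer is
simulated as an independently drawn mirrored head model, since only a
unilateral placement is measured.

Residual sensitivity has the closed form 20·log10|1 − g·e^{iφ}| with
g = 10^(gain error/20); it worsens monotonically in each error argument
on [0°, 180°].  With transfers estimated by a noiseless simulated
measurement, the weight error is bounded by one full quantization step
per component (two half-step roundings from the two independently
measured paths), so the guaranteed per-frequency suppression is
20·log10|1 − 10^{0.02}·e^{i2°}| ≈ −27.4 dB, while the typical frequency
does better than −30 dB (median ≈ −37 dB in the default run).  A
blanket ≥30 dB claim at *every* frequency is not provable under 0.2 dB /
2° quantization and is not asserted.

## Problem sizes and determinism

The default study sizes follow the measurement design: experiment 1 is
156 frequencies in 8 bands measured once; experiment 2 is 8 sittings × 8
frequencies per participant, with cohorts of 3 simulated participants
for the population-level comparisons.  Every random element — model
draw, session perturbations, perceptual noise, presentation order —
derives from explicit integer seeds (`model_seed`, `run_seed`), and
identical configurations reproduce byte-identical trial records.

## What passing tests show — and what they do not

The synthetic experiments validate the *pipeline*: that the unwrapping,
stitching, subtraction and statistics recover a known ground truth under
quantization, perceptual noise and coupling jitter, and that the
variability and grading patterns the procedure is expected to produce do
emerge from the modelled mechanisms.  They cannot validate the
physiological claims themselves: the transfer functions are drawn from a
parametric family, real skulls need not follow it; perceptual noise is
Gaussian and per-adjustment, real listeners drift and learn; the
earphones are assumed perfectly matched and isolating; and binaural
interactions at low frequencies are folded into a noise multiplier
rather than modelled.  Agreement of recovered curves with the model
truth is therefore a statement about the method's self-consistency, not
about any particular head.
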