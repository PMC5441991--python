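# bccancel

Psychoacoustic measurement of bilateral bone-conduction transmission, as a
simulated, testable pipeline — and the cross-talk canceller it enables.

## The problem

A bone transducer (BT) on one mastoid vibrates the whole skull, so both
cochleae hear it.  For bilateral bone-anchored hearing aid (BAHA) users this
interaural cross-talk erodes the benefit of the second implant.  Cross-talk
could be cancelled per frequency — drive the transducer on the far side with
a matched-level, opposite-phase copy — but that requires knowing the complex
transfer (level and phase) from each transducer to each cochlea, which is
not directly measurable in a living head.

A psychoacoustic route exists: present an air-conducted (AC) probe through
an insert earphone and let the listener adjust its level (by maximising
beating against a 1-Hz-detuned tone: beats are strongest when the two tones
match at the basilar membrane) and then its phase (to perceived silence).
At cancellation the AC drive mirrors the bone-conducted signal, so the
cancellation settings *are* the measurement.  Sweeping frequency in 50 Hz
steps from 0.25 to 8 kHz over 8 one-hour sittings, unwrapping the modulo-360
phases within and across sittings, and subtracting the two ears yields the
**inter-cochlear phase difference** (ICPD) and **level difference** (ICLD,
positive = ipsilateral louder) of bone-conducted sound.

This package implements every stage of that methodology over a synthetic
head, so the whole chain can be tested against ground truth:

- `bccancel.head_model` — phenomenological bilateral BC/AC transfer
  functions with the reported structure (near-antiphase temporal-bone
  motion below 1 kHz; steep ICPD accumulation to 4 kHz, then a linear rise;
  narrow >10 dB anti-resonance notches; per-sitting coupling jitter);
- `bccancel.psychophysics` — a virtual participant executing the
  level-match / phase-null / refine / grade procedure on quantized scroll
  steps (0.2 dB, 2°) with perceptual noise;
- `bccancel.analysis` — grade-1 exclusion, modulo-360 unwrapping, band
  stitching (minimal 360-multiple boundary rule, 250 Hz anchor),
  inter-cochlear profiles and across-sitting variability statistics;
- `bccancel.canceller` — per-frequency weights `w = -H_src,off / H_aux,off`
  and the closed-form residual under weight error, `20·log10|1 − g·e^{iφ}|`.

## Worked example

The numbered scripts under `analysis/` run the full study and write plain
CSV/JSON tables under `results/`:

```sh
python analysis/01_simulate_sessions.py   # exp 1 + three exp-2 participants
python analysis/02_unwrap_and_profile.py  # unwrap, stitch, ICPD/ICLD
python analysis/03_session_variability.py # across-sitting SDs, paired tests
python analysis/04_design_canceller.py    # bilateral canceller weights
```

Output of a run with the default seed:

```
experiment 1: 312 records (1 trials graded 1, to be excluded)
profile: 155 retained frequencies, 1 trials excluded
largest raw between-sitting steps: 134.0 deg, 6.0 dB
phase SD ipsi vs contra: t=-5.65, p=0.0000 (n=24 frequency-participant pairs)
contra phase SD vs frequency: Spearman rho=0.84
mean grade minimal at 1000 Hz, maximal at 7000 Hz
cross-talk suppression from quantized measurements: median -36.7 dB, worst -29.3 dB
```

Reading those numbers: raw per-ear series jump by up to 134° / 6 dB where
sittings meet (coupling changes between placements), yet the subtraction
removes them — the inter-cochlear profile is coupling-invariant.  The
contralateral phase SD across sittings is significantly larger than the
ipsilateral (t = −5.65 paired over frequency × participant) and grows with
frequency, the signature of placement sensitivity of the cross-skull path.
Grades are worst at 1 kHz (lateralized beats make level matching hard) and
best near 7 kHz.  Feeding noiselessly measured transfers of two mirrored
heads into the filter design suppresses cross-talk by ≥29 dB at every
frequency, limited only by the 0.2 dB / 2° setting quantization.

A `bccancel` command-line tool exposes the same pipeline
(`bccancel simulate | analyze | design-canceller`, each with `--seed`;
exit codes: 0 success, 1 warnings, 2 config error, 3 data error).

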