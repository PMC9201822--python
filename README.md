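# oddball-eeg

Simulation and analysis pipeline for an audio-visual oddball EEG
experiment: event-related potential (ERP) preprocessing and averaging,
component peak statistics, and single-trial event detection with
variance / spectral / wavelet features and a linear support-vector
machine.

## The problem

In a VR safety scenario, boxes travel a conveyor belt and occasionally
explode or catch fire (rare deviants among standard trials — an oddball
paradigm).  The EEG response to such naturalistic stimuli is a visual
evoked potential (P1) followed by an ERP complex (N2c, P3b) over the
occipital-parietal cortex, and congruent sound alters it: the P1 is
suppressed while N2c/P3b are enhanced.  A brain-computer interface that
detects such safety events must work from single trials, so the
questions are (i) what the average responses look like per modality and
(ii) how well a linear classifier separates stimulus from control
trials under different feature extractions.

The original recordings are not public.  This package therefore ships a
**synthetic-session generator** whose defaults encode the published
session structure (8 blocks × 30 × 6 s trials; 40/40/160
explosion/burning/control), evoked components with the published
amplitudes/latencies at channel O2, a 24-channel 10–20 montage at
250 Hz, and a realistic nuisance model (1/f background, posterior alpha,
50/100 Hz line noise, drift, frontal blinks) — so every stage of the
analysis is testable at desk scale.  It is aimed at BCI/EEG-methods
researchers who want a verifiable reference implementation of this
style of pipeline.

## The pipeline

```
simulate → preprocess → erp → features → classify → report
```

* **simulate** — schedule with exact per-condition counts; evoked
  templates s(t) = a·exp(−(t−μ)²/2σ²) with Gaussian scalp falloff;
  EDF + event-TSV output.
* **preprocess** — drop bad channels (O1, PO7); 50/100 Hz notches +
  0.5–40 Hz zero-phase FIR band-pass; epochs −0.5…+1 s (375 samples);
  pre-onset baseline; ocular removal (regression or seeded FastICA,
  optional); robust variance/kurtosis trial rejection (z > 3).
* **erp** — 38-trial subject averages, grand average (mean ± SD across
  subjects), peak measures at O2 (P1 max 50–180 ms, N2c min 200–400 ms,
  P3b max 400–660 ms), Welch's t-tests
  t = (m̄₁−m̄₂)/√(s₁²/n₁+s₂²/n₂) with Welch–Satterthwaite df, scalp
  snapshots at 120/320/540 ms.
* **features** — on 0–660 ms over 11 parieto-occipital channels:
  VAR (4 windows × 11 = 44), Welch PSD 1–30 Hz (25 bins × 11 = 275),
  db8 level-3 DWT approximations (31 × 11 = 341), fused DVP (660).
* **classify** — balanced stimulus-vs-control sets, 10 repeated
  stratified 80/20 splits, fold-internal [−1, 1] normalization, linear
  SVM; accuracy/specificity/sensitivity per method, audio-visual minus
  visual-only deltas, fold-wise Welch tests.

See `docs/methods.md` for the model, defaults and numerical choices.

## Worked example

The numbered drivers under `analysis/` run the chain at full scale
(8 subjects per modality; ~5 minutes total, large intermediates under
`scratch/`):

```bash
python analysis/01_simulate_sessions.py --seed 0
python analysis/02_preprocess.py       --seed 0
python analysis/03_erp_statistics.py   --seed 0
python analysis/04_features.py         --seed 0
python analysis/05_classify.py         --seed 0
python analysis/06_report.py           --seed 0
```

With seed 0 this prints grand-average O2 peaks

```
visual_only  explosion P1 +12.1@128ms, N2c -15.9@312ms, P3b +4.3@460ms
audio_visual explosion P1  +3.7@100ms, N2c -12.0@324ms, P3b +7.0@544ms
visual_only  burning   P1  +4.1@92ms,  N2c  -3.3@280ms, P3b +3.1@508ms
audio_visual burning   P1  +2.1@64ms,  N2c  -5.0@336ms, P3b +4.0@556ms
```

— the injected cross-modal pattern recovered through the full chain:
the explosion P1 collapses from ~12 to ~4 a.u. under added sound while
the burning N2c/P3b grow.  The detection stage then reports (DVP =
fused VAR+PSD+DWT features):

```
  DVP  explosion  -1.29 pp (p=0.0005)
  DVP  burning    +6.81 pp (p=0.0002)
```

i.e. with congruent audio the fused-feature accuracy for the subtle
burning event improves by ~7 percentage points (81.4 % → 88.2 %) while
the already-easy explosion loses ~1 point — the qualitative effect the
experiment was designed to expose.  Tables land in `results/`
(`erp_peaks.json`, `modality_welch_tests.tsv`, `detection_report.tsv`).

The same chain is scriptable via the CLI:

```bash
oddball-eeg all --seed 0 --out scratch/run     # or per stage:
oddball-eeg simulate --config my_config.yaml
```

## Acceptance script

`scripts/acceptance.py` re-derives the parameter-recovery quantities
from scratch: for each target it simulates replicate 8-subject cohorts
with the shipped presets and default noise, runs the full preprocessing
and averaging chain, and measures the component peak at O2 on the grand
average — P1 and N2c of the visual-only explosion cohort, and P3b of
the audio-visual burning cohort (means over 6 replicate cohorts,
~6 minutes):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
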