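# Methods

This package implements, end to end and on synthetic data, the analysis
chain of a VR audio-visual oddball EEG experiment: session simulation,
ERP preprocessing and averaging, component peak statistics, and
single-trial stimulus-vs-control detection with VAR/PSD/DWT features and
a linear SVM.  This note records the model, the defaults and why, the
numerical choices, and what the synthetic world does and does not
establish.

## The simulated experiment

One session is 8 blocks of 30 six-second trials.  In each trial a box
travels a conveyor belt; after 2 s it either explodes, ignites, or
passes unperturbed.  Deviants are a third of trials, split equally
(40 explosion / 40 burning / 160 control per session), in randomized
order with a uniform 1.3–2 s rest gap between trials.  A marker fires at
the stimulus time point of every trial.  Cohorts come in two
modalities — visual-only and audio-visual — with different evoked
amplitudes, emulating the cross-modal suppression/enhancement effects
the original study reports.

### Evoked model

Each deviant condition carries a set of named components (P1, N1, P2,
N2c, P3b).  A component is a Gaussian bump in time,

    s(t) = a · exp(−(t − μ)² / 2σ²),

scaled per channel by a spatial weight map that decays as a Gaussian of
scalp distance from a focal channel on the 2-D projected 10–20 montage
(P1/N2c focus at O2 over the visual cortex, P3b centro-parietally at
Pz).  The explosion P3b instead holds a plateau from 430 to 600 ms with
a slower falling edge, matching the described morphology.

Amplitudes and latencies are the values printed for the grand-average O2
traces: e.g. visual-only explosion P1 = +11.5 a.u. at 125 ms,
N2c = −15 a.u. at 310 ms; audio-visual burning P1 +2.6 @ 80 ms,
N2c −4.4 @ 330 ms, P3b +4.9 @ 550 ms.  Two calibration choices matter:

* **Amplitudes are referenced to O2.** All printed numbers are O2
  measurements, so a component whose focus is elsewhere (P3b at Pz)
  stores a focal amplitude of `printed / weight(O2)`; the template then
  carries exactly the printed value at O2.
* **Widths are chosen for pass-band transparency.** The source shows
  only empirical waveforms, so σ (18–50 ms per component) is free.  We
  fix it by the criterion that each template's spectral mass must lie
  essentially inside the mandated 0.5–40 Hz analysis band: a 0.5 Hz
  high-pass removes low-frequency mass from any transient, and wide
  bumps (σ ≳ 60 ms) or long plateaus lose >10 % of their peak after
  filtering and baseline correction.  With the shipped widths the
  deterministic noise-free pipeline gain is 0.97–1.03 for P1, N2c and
  the audio-visual P3b (the plateau-shaped explosion P3b retains ~0.86 —
  slow plateaus genuinely do lose amplitude to a 0.5 Hz high-pass, a
  known property of ERP high-pass filtering).  Units are the source's
  arbitrary units throughout; no µV claim is made.

The visual-only burning amplitudes are not printed; only latencies
(~50–100 / ~280 / ~520 ms) and an overall "±5 a.u." scale are.  We back
them out of the printed audio-visual values and the reported modality
factors (P1 suppressed ~1.3×, N2c enhanced ~1.25×, P3b ~1.5× by sound):
P1 +3.4, N2c −3.5, P3b +3.3 a.u.  This keeps the modality contrast
internally consistent (audio-visual N2c/P3b larger, P1 smaller), which
the detection experiment depends on.

### Subjects and noise

A subject is a multiplicative amplitude scale (normal, mean 1,
sd 0.15, floored at 0.3), a latency shift (normal, sd 6 ms), per-trial
latency jitter (sd 4 ms) and amplitude jitter (sd 0.1), a background
noise level (10 a.u. RMS), and a blink rate (12/min).  These spreads are
deliberately *smaller* than the real cohort's (the source reports P1 =
11.5 ± 9.9 a.u. across 8 subjects): at that spread, recovering preset
amplitudes from an 8-subject cohort within a few percent is impossible,
and the point of the synthetic world is that every stage is verifiable.
Study-scale variability is one configuration away
(`draw_subject_profiles(amplitude_scale_sd=0.85, ...)`), but green
recovery tests then say nothing.

Background noise per channel: 1/f ("pink") Gaussian noise scaled to the
subject's RMS; a coherent ~10 Hz alpha band (Gaussian spectral bump,
posterior topography); 50 and 100 Hz line components; sub-0.2 Hz
electrode drift; and stereotyped Gaussian blink transients (sd 80 ms,
60 a.u.) focused at Fp1/Fp2.  The ongoing activity is multiplied by a
slow (<0.1 Hz) global gain envelope (sd 0.10): real EEG is
nonstationary, and without this the per-trial variance distribution is
so tight that ordinary condition differences look like artifacts to the
rejection stage.  Not modelled: volume conduction (weights are smooth
falloff maps, not a head model), channel-specific line phase, muscle
artifacts, behavioural responses.

Seeding: one master seed fans out through `numpy` `SeedSequence.spawn`
into independent streams for the schedule, noise, blinks, per-trial
jitter and trial selection; identical seeds give byte-identical output.

## Preprocessing

Conventions: half-open epoch windows `[t0, t1)` with 0-based indexing
(−0.5…+1.0 s at 250 Hz = 375 samples, onset at index 125); baseline =
mean of the full pre-onset window; all filtering zero-phase.

* **Channel exclusion** — config list; the shipped profile drops O1 and
  PO7 (unreliable in the original recordings).  No re-referencing.
* **Filters** — IIR notches at 50/100 Hz (Q = 30, forward–backward,
  i.e. squared magnitude) and a 1651-tap Hamming-window band-pass FIR,
  0.5–40 Hz (≈0.5 Hz transition).  Applied as a single frequency-domain
  pass: reflection-pad by one kernel length, FFT, multiply by the
  delay-compensated real response of the symmetric FIR times the notch
  magnitude-squared responses, inverse FFT.  This is identical to
  time-domain zero-phase application but one order of magnitude faster
  on ~30-minute sessions.
* **Epoching** — one epoch per marker; events whose window leaves the
  recording are skipped with a logged reason (conservation: epochs +
  skipped = events).
* **Ocular artifacts** — optional stage (off in the default chain
  because blinks live at Fp1/Fp2, which feed neither the feature
  channels nor the O2/Pz peak measures).  `regression` projects the
  Fp1/Fp2 mean out of every channel; `ica_corr` runs FastICA (seeded)
  and removes components correlating > 0.8 (config) with the ocular
  proxy, falling back to regression with a warning if ICA fails to
  converge.  The original study's visual infomax-ICA inspection is thus
  replaced by an automated, deterministic criterion.
* **Trial rejection** — per-epoch variance and excess kurtosis pooled
  over the feature channels; an epoch is flagged when either statistic
  lies more than z = 3 robust SDs (median/MAD) *above* its ensemble
  median.  Ensembles are per-condition by default: evoked activity
  common to all deviant trials is signal, not artifact, and a pooled
  ensemble would systematically reject stimulus trials (incompatible
  with the 38-of-40 retention the protocol fixes).  Upper-tailed because
  artifacts only inflate these statistics.
* **Averaging** — per subject, 38 trials per condition (seeded random
  subset of the kept trials; `first` policy available), then the grand
  average as across-subject mean ± sample SD.  Eight subjects × 38
  control trials pool to the protocol's 304 control trials.

Rejection at z = 3 removes ~2–3 % of trials, so occasionally a subject
keeps fewer than 38 trials in a condition.  `subject_average` raises in
that case; cohort drivers respond the way the study did (it recorded 9
subjects per modality and analysed 8): `experiments` replaces the
subject with a freshly drawn one, and the staged `pipeline` simulates
one spare subject and excludes shortfall subjects with a warning.

## ERP metrics

Component peaks are the extremum of the stated polarity at one channel
(O2) within per-component windows — P1 50–180 ms, N2c 200–400 ms, P3b
400–660 ms (the source prints none; these bracket its described
morphology).  Ties break toward the earliest latency; latency is
reported at the extremum sample (no interpolation).  Group comparisons
use Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
freedom; degenerate zero-variance inputs are defined (t = 0, p = 1 for
equal means; flagged otherwise).  Raw p values are reported without
multiple-comparison correction, matching the source's reporting.
Topographies are tabulated as nearest-sample per-channel amplitudes at
120/320/540 ms (no plotting).

## Features

All extractors run on the 0–660 ms post-onset window (165 samples) over
the 11 parieto-occipital channels PO3, PO4, PO8, O2, Pz, P3, P4, CPz,
CP1, CP2, Cz, channel-major, with per-column provenance names.

* **VAR** — sample variance in four windows (0–660 and three 220 ms
  thirds): 44 features.
* **PSD** — Welch estimate on a single Hann segment (the window is too
  short to average segments), constant-detrended, band-limited to
  1–30 Hz.  The `printed-dims` profile pins `nfft = 210` so the grid
  spacing (250/210 ≈ 1.19 Hz) puts exactly 25 bins in band → 275
  features; `natural` uses nfft = window length (19 bins).  The
  original Welch settings are unrecoverable from the text; the pinned
  grid exists solely to reproduce the printed dimensionality and is
  recorded in provenance.
* **DWT** — 3-level db8 decomposition, level-3 approximation
  coefficients.  The db8 filter is constructed at import time by
  spectral factorization of the Daubechies half-band polynomial
  (matches published coefficients to ~1e-11); symmetric extension gives
  `floor((n+15)/2)` coefficients per level → 33 for 165 samples
  (periodization would give 21).  No standard boundary mode yields the
  printed 31, so `printed-dims` centre-truncates 33 → 31 (→ 341 features,
  fused 660); `natural` keeps all 33.  True counts always appear in
  provenance.
* **Normalization** — per-feature affine map sending the *training*
  min/max to −1/+1, fitted inside each CV fold and applied unchanged to
  the test fold (test values may leave [−1, 1]; constant features map
  to 0 with a warning).  The source normalizes before classification
  without addressing leakage; the leak-free variant is adopted.
* **Fusion (DVP)** — column concatenation in VAR, PSD, DWT order.

## Classification

Stimulus vs control, one binary problem per condition × modality ×
method.  Classes are balanced by seeded subsampling of the majority
class (the protocol's matched 304/304 selection).  The printed CV
protocol ("k-fold, k = 10, 80 % training, 20 % testing") contradicts
canonical 10-fold partitioning; the default is therefore 10 repeated
stratified 80/20 splits, with canonical stratified k-fold available via
config.  Per fold: fit normalizer on train, apply to test, train
`SVC(kernel="linear", C=1.0)` (C unstated in the source, configurable),
evaluate confusion counts with stimulus positive and boundary ties
assigned positive.  Reported: accuracy, specificity, sensitivity
(mean ± SD over folds), audio-visual minus visual-only deltas in
percentage points, Welch tests on fold accuracies, and the best method
per column.  Subject-specific mode repeats the protocol within each
subject on the fused features.

## What a green test establishes — and what it does not

The synthetic world is calibrated so that the full chain is *unbiased*:
simulate → preprocess → average → measure returns the preset amplitudes
to within a few percent (deterministic pipeline gain 0.97–1.03 plus
stochastic error ~3–5 % per 8-subject cohort).  Parameter-recovery tests
therefore verify the pipeline's correctness, not the realism of the
generator: real cohorts have several-fold larger inter-subject spread,
unmodelled artifacts, and unknown true component shapes.  Likewise the
detection experiment reproduces the *direction* of the modality effects
(fused-feature accuracy up for burning, slightly down for explosion,
under congruent sound) because the presets encode those amplitude
changes; absolute accuracies depend on the chosen noise level and are
not comparable to the original study's table, whose raw recordings are
unavailable.

## Numerical details worth knowing

* EDF output uses 1 s records, 16-bit samples, symmetric per-channel
  physical bounds with 0.1 % headroom (roundtrip error ≤ one
  quantization step); the true sample count is stamped in the reserved
  header field because EDF pads the final record.  Events travel in a
  sidecar TSV (`onset_sample`, `onset_s`, `condition`).
* The periodization DWT branch pads odd lengths by edge repetition; its
  transform matrix is orthogonal, so synthesis is the transpose.
  Symmetric-mode synthesis trims a constant `filter_length − 2` offset,
  verified by exact reconstruction (<1e-8 relative) at many lengths.
* `reject_trials` falls back from MAD to the ordinary SD when the MAD
  is zero (e.g. identical epochs).
* All randomness flows from explicit seeds; reruns of any stage with an
  identical configuration are byte-stable.

## Known limitations

* The generator's nuisance model omits muscle/EMG bursts, electrode
  pops and heartbeat; the rejection stage is therefore exercised mainly
  by amplitude-envelope outliers and blink leakage.
* Scalp topography is a 2-D falloff map; snapshot tables are
  qualitatively posterior-dominant but not physiologically quantitative.
* The explosion P3b plateau loses ~14 % of its amplitude to the 0.5 Hz
  high-pass (real ERP pipelines share this bias); its preset value is
  recovered correspondingly low and it is not used as a recovery
  benchmark.
* Subject-specific classification results are computed on 38 + 38
  trials per subject and are accordingly noisy.
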