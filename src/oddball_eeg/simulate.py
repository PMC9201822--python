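"""Synthetic audio-visual oddball EEG sessions.

One simulated session emulates a VR conveyor-belt experiment: 8 blocks of
30 six-second trials, with rare deviant events (an exploding or a burning
box, together one third of trials, split equally) embedded in a stream of
control trials.  A trigger marks the stimulus time point of every trial.
Deviant trials carry condition-specific evoked components (P1, N1, P2,
N2c, P3b) with a posterior scalp topography; control trials carry none.

The background model is deliberately simple but covers the nuisance
structure the analysis pipeline has to survive: 1/f ("pink") broadband
noise, a coherent posterior alpha rhythm, 50/100 Hz line interference,
sub-0.2 Hz electrode drift, and stereotyped blink transients dominant at
the frontal-polar channels.  Volume conduction is reduced to smooth
Gaussian falloff maps on the 2-D montage; no head model is implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CHANNELS, gaussian_topography

__all__ = [
    "SessionConfig",
    "SessionSchedule",
    "ComponentTemplate",
    "ConditionPreset",
    "SubjectProfile",
    "NoiseConfig",
    "ContinuousRecording",
    "build_schedule",
    "evoked_waveform",
    "synthesize_recording",
    "simulate_session",
    "draw_subject_profiles",
    "CONDITIONS",
]

CONDITIONS = ("explosion", "burning", "control")


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Accept ints, None, or an existing SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# --------------------------------------------------------------------------
# configuration / domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionConfig:
    """Trial bookkeeping of one recording session."""

    n_blocks: int = 8
    trials_per_block: int = 30
    trial_duration_s: float = 6.0
    deviant_fraction: float = 1.0 / 3.0
    sampling_rate: float = 250.0
    inter_trial_gap_s: tuple[float, float] = (1.3, 2.0)
    #: the stimulus (marker) fires this long after the trial starts, when
    #: the box reaches the event position on the belt
    stimulus_delay_s: float = 2.0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("block/trial counts must be positive")
        if not (0.0 <= self.deviant_fraction <= 1.0):
            raise ValueError("deviant_fraction must lie in [0, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.inter_trial_gap_s
        if not (0.0 <= lo <= hi):
            raise ValueError("inter_trial_gap_s must be an ordered non-negative range")
        if not (0.0 <= self.stimulus_delay_s < self.trial_duration_s):
            raise ValueError("stimulus_delay_s must fall inside the trial")
        n_dev = round(self.deviant_fraction * self.n_trials)
        if n_dev % 2:
            raise ValueError(
                f"deviant_fraction {self.deviant_fraction} yields {n_dev} deviant "
                f"trials for {self.n_trials} total, which cannot be split equally "
                "between the explosion and burning conditions"
            )


@dataclass(frozen=True)
class SessionSchedule:
    """Randomized trial order with stimulus-onset times (seconds)."""

    labels: tuple[str, ...]
    onsets_s: np.ndarray          # stimulus/marker times
    trial_starts_s: np.ndarray
    config: SessionConfig

    @property
    def n_trials(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in CONDITIONS}

    @property
    def duration_s(self) -> float:
        return float(self.trial_starts_s[-1] + self.config.trial_duration_s)


@dataclass(frozen=True)
class ComponentTemplate:
    """One evoked component: a unimodal bump with a spatial weight map.

    ``width_ms`` is the Gaussian standard deviation of the bump.  If
    ``plateau_end_ms`` is set the component rises to its peak, holds the
    peak value until ``plateau_end_ms`` and then decays with a slower
    (2x width) half-Gaussian — the extended-plateau morphology of a late
    P3b.  ``peak_amplitude`` is a magnitude; the sign comes from
    ``polarity``.
    """

    name: str
    polarity: int
    peak_amplitude: float
    peak_latency_ms: float
    width_ms: float
    topography: dict[str, float]
    plateau_end_ms: float | None = None

    def validate(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude is a magnitude (sign via polarity)")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        for ch, w in self.topography.items():
            if ch not in CHANNELS:
                raise ValueError(f"topography references unknown channel {ch!r}")
            if abs(w) > 1.0 + 1e-12:
                raise ValueError(f"|topography weight| at {ch} exceeds 1")
        if not math.isclose(max(self.topography.values()), 1.0, abs_tol=1e-9):
            raise ValueError("topography must peak at 1 at its focal channel")
        if self.plateau_end_ms is not None and self.plateau_end_ms < self.peak_latency_ms:
            raise ValueError("plateau_end_ms must not precede peak_latency_ms")

    @property
    def focal_channel(self) -> str:
        return max(self.topography, key=self.topography.get)

    def signed_amplitude(self) -> float:
        return self.polarity * self.peak_amplitude

    def time_course(self, t_ms: np.ndarray, latency_shift_ms: float = 0.0,
                    amplitude_scale: float = 1.0) -> np.ndarray:
        """Temporal profile at unit topography weight."""
        mu = self.peak_latency_ms + latency_shift_ms
        amp = self.signed_amplitude() * amplitude_scale
        s = self.width_ms
        if self.plateau_end_ms is None:
            return amp * np.exp(-((t_ms - mu) ** 2) / (2.0 * s * s))
        end = self.plateau_end_ms + latency_shift_ms
        out = np.empty_like(t_ms, dtype=float)
        rise = t_ms < mu
        fall = t_ms > end
        out[rise] = np.exp(-((t_ms[rise] - mu) ** 2) / (2.0 * s * s))
        out[~rise & ~fall] = 1.0
        out[fall] = np.exp(-((t_ms[fall] - end) ** 2) / (2.0 * (2.0 * s) ** 2))
        return amp * out


@dataclass(frozen=True)
class ConditionPreset:
    """Evoked-response recipe for one condition in one modality."""

    condition: str
    modality: str
    components: tuple[ComponentTemplate, ...] = ()

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.modality not in ("visual_only", "audio_visual"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.condition == "control" and self.components:
            raise ValueError("the control preset must have no components")
        for c in self.components:
            c.validate()
            limit = 1000.0 if c.plateau_end_ms is not None else 660.0
            if not (0.0 < c.peak_latency_ms <= 660.0):
                raise ValueError(f"{c.name}: peak latency outside (0, 660] ms")
            if c.plateau_end_ms is not None and c.plateau_end_ms > limit:
                raise ValueError(f"{c.name}: plateau extends past 1000 ms")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject deviations from the canonical preset."""

    subject_id: str
    amplitude_scale: float = 1.0
    latency_shift_ms: float = 0.0
    latency_jitter_sd_ms: float = 4.0   # per-trial
    trial_amplitude_jitter_sd: float = 0.1  # per-trial multiplicative
    noise_level: float = 10.0           # pink-background RMS, a.u.
    blink_rate_per_min: float = 12.0

    def validate(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.noise_level < 0 or self.latency_jitter_sd_ms < 0:
            raise ValueError("noise_level and jitter sd must be non-negative")
        if self.trial_amplitude_jitter_sd < 0 or self.blink_rate_per_min < 0:
            raise ValueError("jitter/blink parameters must be non-negative")


@dataclass(frozen=True)
class NoiseConfig:
    """Amplitudes (a.u.) of the structured background components.

    The broadband pink floor is scaled by ``SubjectProfile.noise_level``;
    everything here is additive structure on top of it.
    """

    pink_exponent: float = 1.0
    alpha_freq_hz: float = 10.0
    alpha_rms: float = 4.0
    alpha_focus: str = "O2"
    alpha_spread: float = 0.55
    #: slow (sub-``modulation_cutoff_hz``) global gain fluctuation of the
    #: ongoing activity — EEG is nonstationary, so per-trial variance
    #: disperses far more than stationary noise would predict
    modulation_sd: float = 0.10
    modulation_cutoff_hz: float = 0.1
    line_freqs_hz: tuple[float, ...] = (50.0, 100.0)
    line_amps: tuple[float, ...] = (4.0, 1.5)
    drift_cutoff_hz: float = 0.2
    drift_rms: float = 15.0
    blink_amplitude: float = 60.0
    blink_width_ms: float = 80.0
    blink_spread: float = 0.35

    @classmethod
    def silent(cls) -> "NoiseConfig":
        """All structured nuisance components off (noise-free limit)."""
        return cls(alpha_rms=0.0, line_amps=(0.0, 0.0), drift_rms=0.0,
                   blink_amplitude=0.0)


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG with event markers."""

    channel_names: list[str]
    sampling_rate: float
    data: np.ndarray                       # channels x samples, a.u.
    events: list[tuple[int, str]]          # (onset_sample, condition)

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("data row count does not match channel list")
        n = self.data.shape[1]
        for s, cond in self.events:
            if not (0 <= s < n):
                raise ValueError(f"event at sample {s} outside recording of {n} samples")
            if cond not in CONDITIONS:
                raise ValueError(f"unknown event condition {cond!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def build_schedule(cfg: SessionConfig, seed: int | None = None) -> SessionSchedule:
    """Randomized trial order with exact per-condition counts.

    The deviant total is ``round(deviant_fraction * n_trials)``, split
    equally between explosion and burning (fixed counts rather than
    per-trial coin flips, matching the stated session totals); the
    remainder is control.  Onsets respect the trial duration and the
    uniform inter-trial rest gap.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = cfg.n_trials
    n_dev = round(cfg.deviant_fraction * n)
    n_each = n_dev // 2
    labels = np.array(
        ["explosion"] * n_each + ["burning"] * n_each + ["control"] * (n - n_dev)
    )
    rng.shuffle(labels)
    lo, hi = cfg.inter_trial_gap_s
    gaps = rng.uniform(lo, hi, size=n - 1) if n > 1 else np.empty(0)
    starts = np.concatenate([[0.0], np.cumsum(cfg.trial_duration_s + gaps)])
    onsets = starts + cfg.stimulus_delay_s
    return SessionSchedule(labels=tuple(labels.tolist()), onsets_s=onsets,
                           trial_starts_s=starts, config=cfg)


def evoked_waveform(preset: ConditionPreset, profile: SubjectProfile,
                    time_grid_s: np.ndarray,
                    channels: list[str] | None = None) -> np.ndarray:
    """Deterministic evoked response (channels x samples) on a post-onset
    time grid, i.e. the superposition of the preset's components under the
    subject's amplitude scale and latency shift (no per-trial jitter)."""
    preset.validate()
    profile.validate()
    chans = channels if channels is not None else CHANNELS
    t_ms = np.asarray(time_grid_s, dtype=float) * 1000.0
    out = np.zeros((len(chans), t_ms.size))
    for comp in preset.components:
        mu = comp.peak_latency_ms + profile.latency_shift_ms
        if not (t_ms[0] <= mu <= t_ms[-1]):
            raise ValueError(
                f"component {comp.name} peak latency {mu:.1f} ms falls outside "
                f"the time grid [{t_ms[0]:.1f}, {t_ms[-1]:.1f}] ms"
            )
        course = comp.time_course(t_ms, latency_shift_ms=profile.latency_shift_ms,
                                  amplitude_scale=profile.amplitude_scale)
        for i, ch in enumerate(chans):
            w = comp.topography.get(ch, 0.0)
            if w != 0.0:
                out[i] += w * course
    return out


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   shaping) -> np.ndarray:
    """Unit-RMS noise with a caller-supplied spectral amplitude shape.

    Synthesized at the next FFT-friendly length and trimmed, purely for
    speed; the spectrum is shaped identically either way.
    """
    from scipy.fft import next_fast_len
    m = next_fast_len(n)
    spec = rng.normal(size=m // 2 + 1) + 1j * rng.normal(size=m // 2 + 1)
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    gain = shaping(freqs)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=m)[:n]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synthesize_recording(schedule: SessionSchedule,
                         presets: dict[str, ConditionPreset],
                         profile: SubjectProfile,
                         noise: NoiseConfig | None = None,
                         seed: int | None = None,
                         channels: list[str] | None = None,
                         padding_s: float = 5.0) -> ContinuousRecording:
    """Render a schedule into a continuous recording for one subject.

    Evoked responses are inserted at every event onset with per-trial
    latency jitter and multiplicative amplitude variability; background
    noise per :class:`NoiseConfig`.  A fixed seed fans out into separate
    streams for noise, jitter and blinks, so the output is reproducible.
    """
    noise = noise if noise is not None else NoiseConfig()
    profile.validate()
    chans = channels if channels is not None else list(CHANNELS)
    cfg = schedule.config
    fs = cfg.sampling_rate
    n_samples = int(math.ceil((schedule.duration_s + 2 * padding_s) * fs))
    for cond in set(schedule.labels):
        if cond not in presets:
            raise ValueError(f"no preset supplied for condition {cond!r}")

    ss = as_seed_sequence(seed)
    rng_noise, rng_trial, rng_blink = (np.random.default_rng(s) for s in ss.spawn(3))

    data = np.zeros((len(chans), n_samples))

    # --- background -------------------------------------------------------
    if profile.noise_level > 0:
        a = noise.pink_exponent
        for i in range(len(chans)):
            pink = _colored_noise(
                rng_noise, n_samples, fs,
                lambda f: np.where(f > 0, f, 1.0) ** (-a / 2.0))
            data[i] += profile.noise_level * pink
    if noise.alpha_rms > 0:
        band = _colored_noise(
            rng_noise, n_samples, fs,
            lambda f: np.exp(-((f - noise.alpha_freq_hz) ** 2) / (2.0 * 1.0**2)))
        weights = gaussian_topography(noise.alpha_focus, noise.alpha_spread, chans)
        for i, ch in enumerate(chans):
            data[i] += noise.alpha_rms * weights[ch] * band
    if noise.modulation_sd > 0 and data.any():
        env = _colored_noise(
            rng_noise, n_samples, fs,
            lambda f: (f < noise.modulation_cutoff_hz).astype(float))
        env = np.maximum(0.2, 1.0 + noise.modulation_sd * env)
        data *= env[None, :]
    t = np.arange(n_samples) / fs
    for f0, amp in zip(noise.line_freqs_hz, noise.line_amps):
        if amp > 0 and f0 < fs / 2:
            phase = rng_noise.uniform(0, 2 * np.pi)
            data += amp * np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phase)
    if noise.drift_rms > 0:
        for i in range(len(chans)):
            drift = _colored_noise(
                rng_noise, n_samples, fs,
                lambda f: (f < noise.drift_cutoff_hz).astype(float))
            data[i] += noise.drift_rms * drift

    # --- blinks -----------------------------------------------------------
    if noise.blink_amplitude > 0 and profile.blink_rate_per_min > 0:
        duration_s = n_samples / fs
        n_blinks = rng_blink.poisson(profile.blink_rate_per_min * duration_s / 60.0)
        w1 = gaussian_topography("Fp1", noise.blink_spread, chans)
        w2 = gaussian_topography("Fp2", noise.blink_spread, chans)
        weights = np.array([(w1[ch] + w2[ch]) / 2.0 for ch in chans])
        weights /= weights.max()
        sd = noise.blink_width_ms / 1000.0
        half = int(round(4 * sd * fs))
        kernel_t = np.arange(-half, half + 1) / fs
        kernel = np.exp(-kernel_t**2 / (2 * sd * sd))
        for _ in range(n_blinks):
            center = int(rng_blink.uniform(0, n_samples))
            amp = noise.blink_amplitude * max(0.2, rng_blink.normal(1.0, 0.2))
            lo = max(0, center - half)
            hi = min(n_samples, center + half + 1)
            seg = kernel[(lo - (center - half)):(hi - (center - half))]
            data[:, lo:hi] += amp * np.outer(weights, seg)

    # --- evoked responses -------------------------------------------------
    events: list[tuple[int, str]] = []
    window_s = 1.2  # covers latencies up to 1000 ms plus decay
    n_win = int(round(window_s * fs))
    local_t = np.arange(n_win) / fs
    for label, onset in zip(schedule.labels, schedule.onsets_s):
        onset_sample = int(round((onset + padding_s) * fs))
        events.append((onset_sample, label))
        preset = presets[label]
        if not preset.components:
            continue
        jitter = float(rng_trial.normal(0.0, profile.latency_jitter_sd_ms)) \
            if profile.latency_jitter_sd_ms > 0 else 0.0
        amp_jit = float(max(0.0, rng_trial.normal(1.0, profile.trial_amplitude_jitter_sd))) \
            if profile.trial_amplitude_jitter_sd > 0 else 1.0
        trial_profile = replace(profile, latency_shift_ms=profile.latency_shift_ms + jitter,
                                amplitude_scale=profile.amplitude_scale * amp_jit,
                                latency_jitter_sd_ms=0.0)
        ev = evoked_waveform(preset, trial_profile, local_t, chans)
        data[:, onset_sample:onset_sample + n_win] += ev[:, :n_samples - onset_sample]

    rec = ContinuousRecording(channel_names=list(chans), sampling_rate=fs,
                              data=data, events=events)
    rec.validate()
    return rec


def simulate_session(cfg: SessionConfig, presets: dict[str, ConditionPreset],
                     profile: SubjectProfile, seed: int | None = None,
                     noise: NoiseConfig | None = None) -> ContinuousRecording:
    """Schedule + synthesis in one call (separate derived seed streams)."""
    ss = as_seed_sequence(seed)
    s_sched, s_rec = ss.spawn(2)
    schedule = build_schedule(cfg, seed=s_sched)
    return synthesize_recording(schedule, presets, profile, noise=noise, seed=s_rec)


def draw_subject_profiles(n_subjects: int, seed: int | None = None,
                          amplitude_scale_sd: float = 0.15,
                          latency_shift_sd_ms: float = 6.0,
                          **profile_kwargs) -> list[SubjectProfile]:
    """Cohort of subject profiles with inter-subject amplitude and latency
    variability centred on the canonical preset (mean scale 1, mean shift 0)."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        scale = float(max(0.3, rng.normal(1.0, amplitude_scale_sd)))
        shift = float(rng.normal(0.0, latency_shift_sd_ms))
        profiles.append(SubjectProfile(subject_id=f"S{i + 1:02d}",
                                       amplitude_scale=scale,
                                       latency_shift_ms=shift,
                                       **profile_kwargs))
    return profiles
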