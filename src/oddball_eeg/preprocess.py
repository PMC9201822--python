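"""Preprocessing pipeline: channel exclusion, filtering, epoching,
baseline correction, ocular-artifact removal, trial rejection and
averaging.

Conventions, stated once and used everywhere:

* epochs use the half-open sampling window ``[t0, t1)`` with 0-based
  sample indexing, so a -0.5..+1.0 s window at 250 Hz has 375 samples and
  the onset sits at index ``round(-t0 * fs)``;
* the baseline is the mean over the entire pre-onset part of the window;
* filters are applied zero-phase (symmetric FIR kernels applied via FFT
  convolution with reflection padding; IIR notches via forward-backward
  filtering), so peak latencies are not shifted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .montage import DEFAULT_EXCLUDED, FEATURE_CHANNELS, OCULAR_CHANNELS
from .simulate import CONDITIONS, ContinuousRecording, as_seed_sequence

log = logging.getLogger(__name__)

__all__ = [
    "FilterSpec", "EpochSet", "GrandAverage",
    "exclude_channels", "apply_filters", "segment_epochs", "baseline_correct",
    "remove_ocular_artifacts", "reject_trials", "subject_average",
    "condition_averages", "grand_average",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Notch + band-pass filtering parameters."""

    notch_freqs_hz: tuple[float, ...] = (50.0, 100.0)
    notch_q: float = 30.0
    bp_low_hz: float = 0.5
    bp_high_hz: float = 40.0
    fir_numtaps: int = 1651  # ~0.5 Hz transition width at 250 Hz

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0.0 < self.bp_low_hz < self.bp_high_hz < nyq):
            raise ValueError("need 0 < bp_low < bp_high < Nyquist")
        if any(f >= nyq for f in self.notch_freqs_hz):
            raise ValueError("notch frequency at or above Nyquist")
        if self.fir_numtaps % 2 == 0:
            raise ValueError("fir_numtaps must be odd (symmetric type-I FIR)")

    def design_fir(self, fs: float) -> np.ndarray:
        return sps.firwin(self.fir_numtaps, [self.bp_low_hz, self.bp_high_hz],
                          pass_zero=False, fs=fs, window="hamming")


@dataclass
class EpochSet:
    """Fixed-length per-trial windows around stimulus onset."""

    epochs: np.ndarray              # trials x channels x samples
    channel_names: list[str]
    sampling_rate: float
    window_s: tuple[float, float]   # relative to onset, half-open
    labels: list[str]
    subject_id: str = ""
    kept: np.ndarray = field(default=None)          # bool per trial
    reject_reasons: list[str] = field(default_factory=list)
    skipped_events: list[tuple[int, str, str]] = field(default_factory=list)
    baseline_corrected: bool = False

    def __post_init__(self):
        if self.kept is None:
            self.kept = np.ones(len(self.labels), dtype=bool)
        if not self.reject_reasons:
            self.reject_reasons = [""] * len(self.labels)
        n, c, s = self.epochs.shape
        if n != len(self.labels) or c != len(self.channel_names):
            raise ValueError("epoch array shape does not match labels/channels")
        if any(lb not in CONDITIONS for lb in self.labels):
            raise ValueError("labels must be one of " + ", ".join(CONDITIONS))

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def onset_index(self) -> int:
        return int(round(-self.window_s[0] * self.sampling_rate))

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.onset_index) \
            / self.sampling_rate * 1000.0

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch set") from None


@dataclass(frozen=True)
class GrandAverage:
    """Across-subject mean and sample SD per condition."""

    means: dict[str, np.ndarray]    # condition -> channels x samples
    sds: dict[str, np.ndarray]
    channel_names: list[str]
    sampling_rate: float
    window_s: tuple[float, float]
    n_subjects: int
    trials_per_subject: int

    @property
    def onset_index(self) -> int:
        return int(round(-self.window_s[0] * self.sampling_rate))

    def times_ms(self) -> np.ndarray:
        n = next(iter(self.means.values())).shape[1]
        return (np.arange(n) - self.onset_index) / self.sampling_rate * 1000.0

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in grand average") from None


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def exclude_channels(rec: ContinuousRecording,
                     exclude: tuple[str, ...] = DEFAULT_EXCLUDED) -> ContinuousRecording:
    """Drop bad channels (config-driven stand-in for visual inspection)."""
    keep = [i for i, ch in enumerate(rec.channel_names) if ch not in exclude]
    return ContinuousRecording(
        channel_names=[rec.channel_names[i] for i in keep],
        sampling_rate=rec.sampling_rate,
        data=rec.data[keep], events=list(rec.events))


def _zero_phase_gain(spec: FilterSpec, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Combined real-valued zero-phase frequency response of the filter
    chain: the delay-compensated response of the symmetric band-pass FIR
    times the squared-magnitude (forward-backward) response of each IIR
    notch."""
    kernel = spec.design_fir(fs)
    m = (len(kernel) - 1) / 2.0
    w = 2.0 * np.pi * freqs / fs
    _, h_fir = sps.freqz(kernel, worN=w)
    gain = np.real(h_fir * np.exp(1j * w * m))  # remove the linear phase
    for f0 in spec.notch_freqs_hz:
        b, a = sps.iirnotch(f0, spec.notch_q, fs=fs)
        _, h = sps.freqz(b, a, worN=w)
        gain = gain * np.abs(h) ** 2
    return gain


def apply_filters(rec: ContinuousRecording, spec: FilterSpec | None = None) -> ContinuousRecording:
    """Notch (50/100 Hz) and band-pass (0.5-40 Hz) the recording, zero
    phase, returning a new recording.

    Applied in the frequency domain (reflection padding by one kernel
    length, FFT, multiply by the chain's zero-phase response, inverse):
    identical to convolving with the symmetric FIR kernel and
    forward-backward notch filtering, but a single pass over the data.
    """
    from scipy.fft import next_fast_len

    spec = spec or FilterSpec()
    spec.validate(rec.sampling_rate)
    if rec.n_samples <= spec.fir_numtaps:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than the "
            f"{spec.fir_numtaps}-tap FIR filter")
    pad = spec.fir_numtaps
    padded = np.pad(rec.data, [(0, 0), (pad, pad)], mode="reflect")
    m = next_fast_len(padded.shape[1] + pad)  # room against circular wrap
    freqs = np.fft.rfftfreq(m, d=1.0 / rec.sampling_rate)
    gain = _zero_phase_gain(spec, freqs, rec.sampling_rate)
    spec_d = np.fft.rfft(padded, n=m, axis=1)
    out = np.fft.irfft(spec_d * gain[None, :], n=m, axis=1)
    data = out[:, pad:pad + rec.n_samples]
    return ContinuousRecording(channel_names=list(rec.channel_names),
                               sampling_rate=rec.sampling_rate,
                               data=data, events=list(rec.events))


def segment_epochs(rec: ContinuousRecording,
                   window_s: tuple[float, float] = (-0.5, 1.0),
                   subject_id: str = "") -> EpochSet:
    """One epoch per event marker; events too close to the recording edges
    are skipped with a logged reason."""
    t0, t1 = window_s
    if not (t0 < 0.0 <= t1):
        raise ValueError("window must contain the onset")
    if not rec.events:
        raise ValueError("recording has no event markers to segment")
    fs = rec.sampling_rate
    pre = int(round(-t0 * fs))
    n_len = int(round((t1 - t0) * fs))  # half-open [t0, t1)
    epochs, labels, skipped = [], [], []
    for onset, cond in rec.events:
        start = onset - pre
        if start < 0 or start + n_len > rec.n_samples:
            reason = "pre-window before recording start" if start < 0 \
                else "post-window past recording end"
            skipped.append((onset, cond, reason))
            log.info("skipping event at sample %d (%s): %s", onset, cond, reason)
            continue
        epochs.append(rec.data[:, start:start + n_len])
        labels.append(cond)
    if not epochs:
        raise ValueError("no events with a fully interior epoch window")
    return EpochSet(epochs=np.stack(epochs), channel_names=list(rec.channel_names),
                    sampling_rate=fs, window_s=window_s, labels=labels,
                    subject_id=subject_id, skipped_events=skipped)


def baseline_correct(es: EpochSet) -> EpochSet:
    """Subtract the mean over the full pre-onset window per epoch and
    channel.  Idempotent."""
    pre = es.onset_index
    if pre < 1:
        raise ValueError("no pre-onset samples available for the baseline")
    base = es.epochs[:, :, :pre].mean(axis=2, keepdims=True)
    return replace(es, epochs=es.epochs - base, baseline_corrected=True,
                   kept=es.kept.copy(), reject_reasons=list(es.reject_reasons))


def _ocular_proxy(data2d: np.ndarray, channel_names: list[str]) -> np.ndarray:
    idx = [channel_names.index(ch) for ch in OCULAR_CHANNELS
           if ch in channel_names]
    if not idx:
        raise ValueError(
            f"ocular proxy channels {OCULAR_CHANNELS} absent from the data")
    return data2d[idx].mean(axis=0)


def remove_ocular_artifacts(data, method: str = "ica_corr",
                            corr_threshold: float = 0.8,
                            seed: int | None = 0,
                            n_components: int | None = None):
    """Remove blink/eye-movement activity using the frontal-polar proxy.

    ``data`` may be a :class:`ContinuousRecording` or an :class:`EpochSet`
    (epochs are concatenated in time for the decomposition and split
    back).  Two automated stand-ins for visual IC selection:

    ``ica_corr``
        FastICA decomposition; components whose absolute correlation with
        the Fp1/Fp2 mean exceeds ``corr_threshold`` are zeroed and the
        signal reconstructed.  Falls back to ``regression`` with a logged
        warning if ICA does not converge.
    ``regression``
        Least-squares projection of the ocular proxy out of each channel.

    Returns ``(cleaned, report)`` where ``report`` lists removed
    components or regression coefficients.
    """
    if isinstance(data, EpochSet):
        n, c, s = data.epochs.shape
        flat = data.epochs.transpose(1, 0, 2).reshape(c, n * s)
        cleaned, report = remove_ocular_artifacts(
            (flat, data.channel_names), method=method,
            corr_threshold=corr_threshold, seed=seed, n_components=n_components)
        out = cleaned.reshape(c, n, s).transpose(1, 0, 2)
        return replace(data, epochs=out, kept=data.kept.copy(),
                       reject_reasons=list(data.reject_reasons)), report
    if isinstance(data, ContinuousRecording):
        cleaned, report = remove_ocular_artifacts(
            (data.data, data.channel_names), method=method,
            corr_threshold=corr_threshold, seed=seed, n_components=n_components)
        return ContinuousRecording(channel_names=list(data.channel_names),
                                   sampling_rate=data.sampling_rate,
                                   data=cleaned, events=list(data.events)), report

    x, channel_names = data
    proxy = _ocular_proxy(x, channel_names)

    if method == "regression":
        denom = float(proxy @ proxy)
        if denom == 0.0:
            return x.copy(), {"method": "regression", "coefficients": {}}
        beta = (x @ proxy) / denom
        cleaned = x - np.outer(beta, proxy)
        return cleaned, {"method": "regression",
                         "coefficients": dict(zip(channel_names, beta.tolist()))}

    if method != "ica_corr":
        raise ValueError(f"unknown method {method!r}")

    from sklearn.decomposition import FastICA
    n_comp = n_components or min(len(channel_names), 20)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ica = FastICA(n_components=n_comp, random_state=seed,
                      max_iter=500, whiten="unit-variance")
        sources = ica.fit_transform(x.T)  # samples x components
        converged = not any("did not converge" in str(w.message).lower()
                            for w in caught)
    if not converged:
        log.warning("FastICA did not converge; falling back to regression")
        cleaned, report = remove_ocular_artifacts(
            (x, channel_names), method="regression")
        report["fallback_from"] = "ica_corr"
        return cleaned, report

    corrs = np.array([
        abs(np.corrcoef(sources[:, k], proxy)[0, 1]) if sources[:, k].std() > 0 else 0.0
        for k in range(n_comp)])
    removed = np.where(corrs > corr_threshold)[0]
    sources_clean = sources.copy()
    sources_clean[:, removed] = 0.0
    cleaned = (sources_clean @ ica.mixing_.T + ica.mean_).T
    return cleaned, {"method": "ica_corr",
                     "removed_components": removed.tolist(),
                     "component_proxy_correlation": corrs.tolist()}


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.std(x) or 1.0
    return (x - med) / scale


def reject_trials(es: EpochSet, z_var: float = 3.0, z_kurt: float = 3.0,
                  channels: tuple[str, ...] | None = None,
                  group_by_condition: bool = True) -> EpochSet:
    """Flag epochs whose variance or kurtosis (pooled over the feature
    channels) lies more than ``z`` robust SDs above the ensemble median.

    Upper-tailed on purpose: artifacts inflate both statistics.  With
    ``group_by_condition`` (default) each epoch is compared to the
    ensemble of its own condition, so evoked activity common to a whole
    condition is not mistaken for an artifact; conditions with fewer than
    8 epochs fall back to the global ensemble.  This is the automated
    stand-in for visual trial inspection.
    """
    if es.n_trials < 3:
        raise ValueError("need at least 3 epochs for ensemble rejection")
    chans = channels or tuple(ch for ch in FEATURE_CHANNELS
                              if ch in es.channel_names) \
        or tuple(es.channel_names)
    idx = [es.channel_index(ch) for ch in chans]
    pooled = es.epochs[:, idx, :].reshape(es.n_trials, -1)
    variances = pooled.var(axis=1)
    kurtoses = spstats.kurtosis(pooled, axis=1, fisher=True)
    labels = np.asarray(es.labels)

    def _z_against(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
        med = np.median(values[ref])
        scale = 1.4826 * np.median(np.abs(values[ref] - med))
        if scale == 0:
            scale = values[ref].std() or 1.0
        return (values - med) / scale

    if group_by_condition:
        zv = np.empty(es.n_trials)
        zk = np.empty(es.n_trials)
        for cond in np.unique(labels):
            sel = labels == cond
            ref = sel if sel.sum() >= 8 else np.ones(es.n_trials, dtype=bool)
            zv[sel] = _z_against(variances, ref)[sel]
            zk[sel] = _z_against(kurtoses, ref)[sel]
    else:
        zv = _robust_z(variances)
        zk = _robust_z(kurtoses)
    kept = es.kept.copy()
    reasons = list(es.reject_reasons)
    for i in range(es.n_trials):
        why = []
        if zv[i] > z_var:
            why.append(f"variance z={zv[i]:.2f}")
        if zk[i] > z_kurt:
            why.append(f"kurtosis z={zk[i]:.2f}")
        if why:
            kept[i] = False
            reasons[i] = "; ".join(why)
    if not kept.any():
        raise ValueError(
            "all epochs rejected; relax z_var/z_kurt or inspect the data")
    log.info("trial rejection: %d of %d epochs flagged", int((~kept).sum()),
             es.n_trials)
    return replace(es, kept=kept, reject_reasons=reasons)


def subject_average(es: EpochSet, condition: str, n_select: int = 38,
                    seed: int | None = None, policy: str = "random"
                    ) -> tuple[np.ndarray, list[int]]:
    """Mean over a fixed-size subset of kept trials of one condition.

    ``policy='random'`` draws a seeded random subset (the shipped default,
    used for both the stimulus conditions and the much larger control
    pool); ``policy='first'`` takes the first ``n_select`` kept trials.
    Returns ``(channels x samples mean, manifest of trial indices)``.
    """
    idx = [i for i, lb in enumerate(es.labels) if lb == condition and es.kept[i]]
    if len(idx) < n_select:
        raise ValueError(
            f"subject {es.subject_id or '?'}: only {len(idx)} kept "
            f"{condition} trials, need {n_select} "
            f"(shortfall of {n_select - len(idx)})")
    if policy == "first":
        chosen = idx[:n_select]
    elif policy == "random":
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(idx, size=n_select, replace=False).tolist())
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    return es.epochs[chosen].mean(axis=0), chosen


def condition_averages(es: EpochSet, n_select: int = 38,
                       seed: int | None = None, policy: str = "random"
                       ) -> dict[str, np.ndarray]:
    """Per-condition subject averages (same trial count per condition)."""
    ss = as_seed_sequence(seed)
    out = {}
    for cond, s in zip(CONDITIONS, ss.spawn(len(CONDITIONS))):
        if cond in es.labels:
            out[cond], _ = subject_average(es, cond, n_select=n_select,
                                           seed=s, policy=policy)
    return out


def grand_average(subject_avgs: list[dict[str, np.ndarray]],
                  channel_names: list[str], sampling_rate: float,
                  window_s: tuple[float, float] = (-0.5, 1.0),
                  trials_per_subject: int = 38) -> GrandAverage:
    """Pointwise mean and across-subject sample SD per condition."""
    if len(subject_avgs) < 2:
        raise ValueError("grand average needs at least 2 subjects")
    conditions = set().union(*(d.keys() for d in subject_avgs))
    shapes = {d[c].shape for d in subject_avgs for c in d}
    if len(shapes) != 1:
        raise ValueError("subject averages have mismatched channel/sample shapes")
    if next(iter(shapes))[0] != len(channel_names):
        raise ValueError("channel list does not match subject averages")
    means, sds = {}, {}
    for cond in conditions:
        stack = np.stack([d[cond] for d in subject_avgs if cond in d])
        if stack.shape[0] < 2:
            raise ValueError(f"condition {cond!r} present for fewer than 2 subjects")
        means[cond] = stack.mean(axis=0)
        sds[cond] = stack.std(axis=0, ddof=1)
    return GrandAverage(means=means, sds=sds, channel_names=list(channel_names),
                        sampling_rate=sampling_rate, window_s=window_s,
                        n_subjects=len(subject_avgs),
                        trials_per_subject=trials_per_subject)
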