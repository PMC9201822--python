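"""Single-trial feature extraction: VAR, Welch PSD, db8 DWT, and fusion.

All three extractors operate on the 0-660 ms post-onset window (165
samples at 250 Hz under the half-open convention) over an ordered list of
11 parieto-occipital channels, and are deterministic.  Feature ordering
is channel-major (all features of the first channel, then the next),
recorded per column in the provenance names.

Two dimensional profiles ship:

``printed-dims``
    Pins the Welch FFT grid (nfft=210) so exactly 25 bins fall in
    [1, 30] Hz (275 PSD features), and centre-truncates the 33
    symmetric-mode level-3 approximation coefficients to 31 (341 DWT
    features), reproducing the printed 44 + 275 + 341 = 660-element fused
    vector.  The underlying Welch segmentation/boundary handling of the
    original analysis is not recoverable, so these dimensions are pinned
    deliberately; see docs/methods.md.
``natural``
    Conventional parameters: nfft equal to the window length and the full
    (untruncated) coefficient set, with the true counts reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from . import wavelets
from .montage import FEATURE_CHANNELS
from .preprocess import EpochSet

log = logging.getLogger(__name__)

__all__ = ["FeatureConfig", "FeatureMatrix", "var_features", "psd_features",
           "dwt_features", "fit_normalizer", "apply_normalizer", "fuse",
           "extract_all"]


@dataclass(frozen=True)
class FeatureConfig:
    channels: tuple[str, ...] = FEATURE_CHANNELS
    window_ms: tuple[float, float] = (0.0, 660.0)
    var_windows_ms: tuple[tuple[float, float], ...] = (
        (0.0, 660.0), (0.0, 220.0), (220.0, 440.0), (440.0, 660.0))
    psd_band_hz: tuple[float, float] = (1.0, 30.0)
    psd_nfft: int | None = 210     # printed-dims grid; None -> window length
    dwt_level: int = 3
    dwt_wavelet_moments: int = 8   # db8
    dwt_mode: str = "symmetric"
    dwt_keep: int | None = 31      # printed-dims truncation; None -> all
    profile: str = "printed-dims"

    @classmethod
    def natural(cls) -> "FeatureConfig":
        return cls(psd_nfft=None, dwt_keep=None, profile="natural")

    def validate(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("feature channels must be unique")
        lo, hi = self.window_ms
        for wlo, whi in self.var_windows_ms:
            if wlo < lo or whi > hi:
                raise ValueError("variance window outside the analysis window")
        if not (0.0 <= self.psd_band_hz[0] < self.psd_band_hz[1]):
            raise ValueError("invalid PSD band")


@dataclass
class FeatureMatrix:
    """Trials x features with per-column provenance and labels."""

    matrix: np.ndarray
    names: list[str]
    labels: list[str]
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.matrix.shape != (len(self.labels), len(self.names)):
            raise ValueError("matrix shape does not match names/labels")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _analysis_slab(es: EpochSet, cfg: FeatureConfig) -> tuple[np.ndarray, list[int]]:
    """Kept epochs restricted to the analysis window and feature channels."""
    cfg.validate()
    missing = [ch for ch in cfg.channels if ch not in es.channel_names]
    if missing:
        raise ValueError(f"epoch set lacks feature channel(s) {missing}")
    fs = es.sampling_rate
    lo, hi = cfg.window_ms
    i0 = es.onset_index + int(round(lo / 1000.0 * fs))
    i1 = es.onset_index + int(round(hi / 1000.0 * fs))  # half-open
    if i0 < 0 or i1 > es.n_samples:
        raise ValueError("analysis window outside the epoch window")
    ch_idx = [es.channel_index(ch) for ch in cfg.channels]
    kept_idx = np.where(es.kept)[0]
    return es.epochs[np.ix_(kept_idx, ch_idx, np.arange(i0, i1))], kept_idx.tolist()


def _labels_of(es: EpochSet, kept_idx: list[int]) -> list[str]:
    return [es.labels[i] for i in kept_idx]


def var_features(es: EpochSet, cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Sample variance per channel in each configured sub-window
    (4 windows x 11 channels = 44 features in the shipped profile)."""
    cfg = cfg or FeatureConfig()
    slab, kept_idx = _analysis_slab(es, cfg)
    fs = es.sampling_rate
    lo = cfg.window_ms[0]
    cols, names = [], []
    for ch_pos, ch in enumerate(cfg.channels):
        for wlo, whi in cfg.var_windows_ms:
            j0 = int(round((wlo - lo) / 1000.0 * fs))
            j1 = int(round((whi - lo) / 1000.0 * fs))
            cols.append(slab[:, ch_pos, j0:j1].var(axis=1))
            names.append(f"var:{ch}:{wlo:g}-{whi:g}ms")
    return FeatureMatrix(matrix=np.column_stack(cols), names=names,
                         labels=_labels_of(es, kept_idx),
                         meta={"method": "VAR", "profile": cfg.profile})


def psd_features(es: EpochSet, cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Welch power spectral density per channel, band-limited.

    The 660 ms window is a single Hann segment (the window is too short
    for meaningful segment averaging); the FFT grid is the configured
    ``psd_nfft``.  Bins with band_lo <= f <= band_hi are retained.
    """
    cfg = cfg or FeatureConfig()
    slab, kept_idx = _analysis_slab(es, cfg)
    fs = es.sampling_rate
    n_win = slab.shape[2]
    nfft = cfg.psd_nfft or n_win
    if nfft < n_win:
        raise ValueError("psd_nfft smaller than the analysis window")
    freqs, pxx = sps.welch(slab, fs=fs, window="hann", nperseg=n_win,
                           noverlap=0, nfft=nfft, axis=2, detrend="constant")
    lo, hi = cfg.psd_band_hz
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"no FFT bins inside the {lo}-{hi} Hz band "
                         f"(grid spacing {fs / nfft:.3g} Hz)")
    kept_f = freqs[mask]
    cols, names = [], []
    for ch_pos, ch in enumerate(cfg.channels):
        for k, f in enumerate(kept_f):
            cols.append(pxx[:, ch_pos, np.where(mask)[0][k]])
            names.append(f"psd:{ch}:{f:.3f}Hz")
    return FeatureMatrix(matrix=np.column_stack(cols), names=names,
                         labels=_labels_of(es, kept_idx),
                         meta={"method": "PSD", "profile": cfg.profile,
                               "nfft": nfft, "bins_per_channel": int(mask.sum()),
                               "df_hz": fs / nfft})


def dwt_features(es: EpochSet, cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Level-``dwt_level`` db8 approximation coefficients per channel.

    The coefficient count is a deterministic function of window length,
    filter length (16 for db8) and boundary mode — 33 for 165 samples
    with symmetric extension, 21 with periodization — and is reported in
    the provenance.  ``dwt_keep`` centre-truncates (printed-dims: 31).
    """
    cfg = cfg or FeatureConfig()
    slab, kept_idx = _analysis_slab(es, cfg)
    filters = wavelets.db_filters(cfg.dwt_wavelet_moments)
    n = slab.shape[2]
    if wavelets.max_level(n, filters.length) < cfg.dwt_level:
        raise ValueError(
            f"{n}-sample window too short for a level-{cfg.dwt_level} "
            f"decomposition with a {filters.length}-tap filter")
    n_coeff = n
    for _ in range(cfg.dwt_level):
        n_coeff = wavelets.coeff_len(n_coeff, filters.length, cfg.dwt_mode)
    keep = cfg.dwt_keep or n_coeff
    if keep > n_coeff:
        raise ValueError(f"dwt_keep={keep} exceeds the {n_coeff} available "
                         "approximation coefficients")
    trim = (n_coeff - keep) // 2
    sl = slice(trim, trim + keep)

    n_trials = slab.shape[0]
    cols = np.empty((n_trials, len(cfg.channels) * keep))
    for ch_pos in range(len(cfg.channels)):
        for tr in range(n_trials):
            coeffs = wavelets.wavedec(slab[tr, ch_pos], cfg.dwt_level,
                                      mode=cfg.dwt_mode, filters=filters)
            cols[tr, ch_pos * keep:(ch_pos + 1) * keep] = coeffs[0][sl]
    names = [f"dwt:{ch}:cA{cfg.dwt_level}[{k}]"
             for ch in cfg.channels for k in range(sl.start, sl.stop)]
    return FeatureMatrix(matrix=cols, names=names,
                         labels=_labels_of(es, kept_idx),
                         meta={"method": "DWT", "profile": cfg.profile,
                               "mode": cfg.dwt_mode, "level": cfg.dwt_level,
                               "native_coeff_count": n_coeff,
                               "kept_per_channel": keep})


# --------------------------------------------------------------------------
# normalization and fusion
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizerBounds:
    mins: np.ndarray
    maxs: np.ndarray
    names: tuple[str, ...]

    @property
    def degenerate(self) -> np.ndarray:
        return self.maxs <= self.mins


def fit_normalizer(train: FeatureMatrix) -> NormalizerBounds:
    """Per-feature min/max learned on training data only."""
    if train.n_trials == 0:
        raise ValueError("cannot fit a normalizer on an empty matrix")
    mins = train.matrix.min(axis=0)
    maxs = train.matrix.max(axis=0)
    n_flat = int((maxs <= mins).sum())
    if n_flat:
        log.warning("%d constant feature(s) will be mapped to 0", n_flat)
    return NormalizerBounds(mins=mins, maxs=maxs, names=tuple(train.names))


def apply_normalizer(bounds: NormalizerBounds, fm: FeatureMatrix) -> FeatureMatrix:
    """Affine map sending the training min/max of each feature to -1/+1.

    Applied unchanged to unseen data, whose values may land outside
    [-1, 1]; constant training features map to 0.
    """
    if tuple(fm.names) != bounds.names:
        raise ValueError("feature names do not match the fitted bounds")
    span = bounds.maxs - bounds.mins
    safe = np.where(bounds.degenerate, 1.0, span)
    out = 2.0 * (fm.matrix - bounds.mins) / safe - 1.0
    out[:, bounds.degenerate] = 0.0
    n_out = int(((out < -1) | (out > 1)).sum())
    if n_out:
        log.debug("%d normalized values fall outside [-1, 1]", n_out)
    return replace(fm, matrix=out, normalized=True,
                   labels=list(fm.labels), names=list(fm.names),
                   meta=dict(fm.meta))


def fuse(fms: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation (order as given; DVP = VAR, PSD, DWT)."""
    if not fms:
        raise ValueError("nothing to fuse")
    n = fms[0].n_trials
    labels = fms[0].labels
    for fm in fms[1:]:
        if fm.n_trials != n or fm.labels != labels:
            raise ValueError("feature matrices cover different trials")
    return FeatureMatrix(
        matrix=np.hstack([fm.matrix for fm in fms]),
        names=[nm for fm in fms for nm in fm.names],
        labels=list(labels),
        normalized=all(fm.normalized for fm in fms),
        meta={"method": "+".join(fm.meta.get("method", "?") for fm in fms),
              "parts": [fm.meta for fm in fms]})


def extract_all(es: EpochSet, cfg: FeatureConfig | None = None
                ) -> dict[str, FeatureMatrix]:
    """VAR, PSD, DWT and their fusion (DVP) for one epoch set."""
    cfg = cfg or FeatureConfig()
    v = var_features(es, cfg)
    p = psd_features(es, cfg)
    d = dwt_features(es, cfg)
    return {"VAR": v, "PSD": p, "DWT": d, "DVP": fuse([v, p, d])}
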