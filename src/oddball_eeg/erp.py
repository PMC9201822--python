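"""ERP peak measurement, Welch's t-test and scalp snapshots.

Peak amplitudes/latencies are read off averaged waveforms at a single
channel (O2 in the shipped profile): the maximum for positive components
(P1, P3b) and the minimum for negative ones (N2c), inside per-component
search windows.  Group comparisons (e.g. visual-only vs audio-visual
subject peaks, or cross-validation fold accuracies) use Welch's unequal-
variance t-test with Welch-Satterthwaite degrees of freedom; no multiple-
comparison correction is applied, matching the reporting convention of
the study this pipeline mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .preprocess import GrandAverage

__all__ = ["PeakMeasure", "WelchTestResult", "DEFAULT_SEARCH_WINDOWS_MS",
           "peak_measure", "peak_from_grand_average", "welch_ttest",
           "scalp_snapshot"]

#: Default component search windows (ms post-onset), chosen from the
#: published average morphology; configurable per call.
DEFAULT_SEARCH_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "P1": (50.0, 180.0),
    "N2c": (200.0, 400.0),
    "P3b": (400.0, 660.0),
}

#: Extremum polarity per component.
COMPONENT_POLARITY = {"P1": +1, "N1": -1, "P2": +1, "N2c": -1, "P3b": +1}


@dataclass(frozen=True)
class PeakMeasure:
    component: str
    channel: str
    amplitude: float          # a.u., signed
    latency_ms: float         # post-onset
    window_ms: tuple[float, float]
    polarity: int


@dataclass(frozen=True)
class WelchTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def peak_measure(avg: np.ndarray, times_ms: np.ndarray, channel_names: list[str],
                 channel: str, window_ms: tuple[float, float], polarity: int,
                 component: str = "") -> PeakMeasure:
    """Extremum of the stated polarity inside a latency window.

    Ties are broken toward the earliest latency (argmax/argmin return the
    first occurrence).  The latency is reported at the extremum sample;
    no sub-sample interpolation.
    """
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    try:
        ci = channel_names.index(channel)
    except ValueError:
        raise KeyError(f"channel {channel!r} not present") from None
    lo, hi = window_ms
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms contains no samples")
    trace = avg[ci, mask]
    twin = times_ms[mask]
    k = int(np.argmax(trace)) if polarity > 0 else int(np.argmin(trace))
    return PeakMeasure(component=component, channel=channel,
                       amplitude=float(trace[k]), latency_ms=float(twin[k]),
                       window_ms=window_ms, polarity=polarity)


def peak_from_grand_average(ga: GrandAverage, condition: str, component: str,
                            channel: str = "O2",
                            window_ms: tuple[float, float] | None = None
                            ) -> PeakMeasure:
    """Convenience: named-component peak on a grand-average condition."""
    window_ms = window_ms or DEFAULT_SEARCH_WINDOWS_MS[component]
    return peak_measure(ga.means[condition], ga.times_ms(), ga.channel_names,
                        channel, window_ms, COMPONENT_POLARITY[component],
                        component=component)


def welch_ttest(sample_a, sample_b) -> WelchTestResult:
    """Two-sided Welch's t-test (unequal variances).

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), df by the
    Welch-Satterthwaite approximation.  Degenerate zero-variance inputs:
    equal means give (t=0, p=1); unequal means are flagged degenerate
    with t = +/-inf, p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    na, nb = a.size, b.size
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return WelchTestResult(t=0.0, df=float(na + nb - 2), p=1.0,
                                   mean_a=ma, mean_b=mb, sd_a=0.0, sd_b=0.0,
                                   n_a=na, n_b=nb)
        return WelchTestResult(t=float(np.sign(ma - mb)) * np.inf,
                               df=float(na + nb - 2), p=0.0,
                               mean_a=ma, mean_b=mb, sd_a=0.0, sd_b=0.0,
                               n_a=na, n_b=nb, degenerate=True)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * spstats.t.sf(abs(t), df)
    return WelchTestResult(t=float(t), df=float(df), p=float(p),
                           mean_a=float(ma), mean_b=float(mb),
                           sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
                           n_a=na, n_b=nb)


def scalp_snapshot(ga: GrandAverage, condition: str,
                   times_ms: tuple[float, ...] = (120.0, 320.0, 540.0)
                   ) -> dict[float, dict[str, float]]:
    """Per-channel amplitudes at the requested post-onset times
    (nearest sample), e.g. for tabulated topographies."""
    grid = ga.times_ms()
    avg = ga.means[condition]
    out: dict[float, dict[str, float]] = {}
    for t in times_ms:
        if not (grid[0] <= t <= grid[-1]):
            raise ValueError(f"time {t} ms outside the epoch window "
                             f"[{grid[0]:.0f}, {grid[-1]:.0f}] ms")
        k = int(np.argmin(np.abs(grid - t)))
        out[t] = {ch: float(avg[i, k]) for i, ch in enumerate(ga.channel_names)}
    return out
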