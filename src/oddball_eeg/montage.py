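"""24-channel 10-20 montage used by the portable recording system.

Channel positions are 2-D polar-azimuthal projections of the standard
10-20/10-10 scalp coordinates onto the unit disc (nose up, +x to the
right).  They are only used to derive smooth spatial falloff weights for
simulated component topographies, so centimetre accuracy is irrelevant;
relative scalp distances are what matters.
"""

from __future__ import annotations

import numpy as np

# 24 channels: frontal pair for ocular proxies, a fronto-central ridge,
# and dense parieto-occipital coverage (the montage is posterior-heavy).
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95),
    "Fp2": (0.31, 0.95),
    "F3": (-0.41, 0.55),
    "F4": (0.41, 0.55),
    "Fz": (0.00, 0.58),
    "FC1": (-0.20, 0.30),
    "FC2": (0.20, 0.30),
    "C3": (-0.52, 0.00),
    "C4": (0.52, 0.00),
    "Cz": (0.00, 0.00),
    "CP1": (-0.20, -0.30),
    "CP2": (0.20, -0.30),
    "CPz": (0.00, -0.29),
    "P3": (-0.41, -0.55),
    "P4": (0.41, -0.55),
    "Pz": (0.00, -0.58),
    "P7": (-0.81, -0.59),
    "P8": (0.81, -0.59),
    "PO3": (-0.27, -0.80),
    "PO4": (0.27, -0.80),
    "PO7": (-0.61, -0.81),
    "PO8": (0.61, -0.81),
    "O1": (-0.31, -0.95),
    "O2": (0.31, -0.95),
}

CHANNELS: list[str] = list(CHANNEL_POSITIONS)

#: Ocular proxy channels (closest to the eyes).
OCULAR_CHANNELS = ("Fp1", "Fp2")

#: Parieto-occipital subset used for feature extraction (11 channels).
FEATURE_CHANNELS = ("PO3", "PO4", "PO8", "O2", "Pz", "P3", "P4", "CPz", "CP1", "CP2", "Cz")

#: Channels excluded from analysis in the shipped profile (unreliable
#: electrodes in the original recordings).
DEFAULT_EXCLUDED = ("O1", "PO7")


def channel_distance(a: str, b: str) -> float:
    """Euclidean distance between two channels in the 2-D projection."""
    xa, ya = CHANNEL_POSITIONS[a]
    xb, yb = CHANNEL_POSITIONS[b]
    return float(np.hypot(xa - xb, ya - yb))


def gaussian_topography(focus: str, sigma: float = 0.5,
                        channels: list[str] | None = None) -> dict[str, float]:
    """Spatial weight map decaying with scalp distance from ``focus``.

    Weight is 1 at the focal channel and exp(-d^2 / (2 sigma^2)) elsewhere,
    with ``sigma`` in units of the head radius.
    """
    if focus not in CHANNEL_POSITIONS:
        raise KeyError(f"unknown focal channel {focus!r}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    chans = channels if channels is not None else CHANNELS
    return {
        ch: float(np.exp(-channel_distance(focus, ch) ** 2 / (2.0 * sigma**2)))
        for ch in chans
    }
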