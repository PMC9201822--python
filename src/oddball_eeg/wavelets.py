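"""Daubechies discrete wavelet transform, self-contained.

No wavelet library is assumed: the db-N scaling filter is constructed at
import time by spectral factorization of the Daubechies half-band
polynomial (minimum-phase root selection), which reproduces the published
db8 coefficients to ~1e-11.  The transform follows the usual mallat
filter-bank scheme with two boundary modes:

``symmetric``
    Half-point symmetric extension by L-1 samples per side; level output
    length is floor((n + L - 1) / 2).  Redundant but perfectly invertible.
``periodization``
    Circular convolution (odd lengths are edge-padded to even first);
    level output length is ceil(n / 2).  The periodic transform matrix is
    orthogonal, so the inverse is its transpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np

__all__ = [
    "daubechies_filter",
    "WaveletFilters",
    "db_filters",
    "dwt",
    "idwt",
    "wavedec",
    "waverec",
    "coeff_len",
    "max_level",
]


def daubechies_filter(n_moments: int) -> np.ndarray:
    """Orthonormal Daubechies scaling filter with ``n_moments`` vanishing
    moments (length ``2 * n_moments``), minimum-phase ("db") variant.

    Normalized so that sum(h) = sqrt(2) and sum(h**2) = 1.
    """
    if n_moments < 1:
        raise ValueError("n_moments must be >= 1")
    if n_moments == 1:  # Haar; no roots to factor
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # Half-band polynomial P(y) = sum_k C(N-1+k, k) y^k, y = sin^2(w/2)
    p_coeffs = [comb(n_moments - 1 + k, k) for k in range(n_moments)]
    y_roots = np.roots(p_coeffs[::-1])
    z_roots = []
    for y in y_roots:
        # y = (2 - z - 1/z)/4  =>  z^2 - (2 - 4y) z + 1 = 0
        c = 1.0 - 2.0 * y
        r = np.sqrt(c * c - 1.0 + 0j)
        z1, z2 = c + r, c - r
        z_roots.append(z1 if abs(z1) < 1 else z2)  # minimum phase
    q = np.poly(z_roots)
    h = np.real(np.convolve(np.poly([-1.0] * n_moments), q))
    h *= np.sqrt(2.0) / h.sum()
    return h


@dataclass(frozen=True)
class WaveletFilters:
    """Analysis/synthesis filter quadruple of an orthonormal wavelet."""

    rec_lo: np.ndarray
    rec_hi: np.ndarray
    dec_lo: np.ndarray
    dec_hi: np.ndarray

    @property
    def length(self) -> int:
        return len(self.rec_lo)


@lru_cache(maxsize=None)
def db_filters(n_moments: int = 8) -> WaveletFilters:
    h = daubechies_filter(n_moments)
    L = len(h)
    rec_lo = h
    rec_hi = np.array([(-1.0) ** k * h[L - 1 - k] for k in range(L)])
    return WaveletFilters(
        rec_lo=rec_lo, rec_hi=rec_hi,
        dec_lo=rec_lo[::-1].copy(), dec_hi=rec_hi[::-1].copy(),
    )


def coeff_len(n: int, filter_len: int, mode: str) -> int:
    """Coefficient count of one analysis level on ``n`` samples."""
    if mode == "symmetric":
        return (n + filter_len - 1) // 2
    if mode == "periodization":
        return (n + 1) // 2
    raise ValueError(f"unknown boundary mode {mode!r}")


def max_level(n: int, filter_len: int) -> int:
    """Deepest useful decomposition level for ``n`` samples."""
    if n < filter_len:
        return 0
    return int(np.floor(np.log2(n / (filter_len - 1.0))))


def _periodic_analysis_matrix(n: int, filt: np.ndarray) -> np.ndarray:
    # rows: even circular shifts, anchored to match the symmetric-mode
    # downsampling phase ([1::2] of the valid convolution)
    L = len(filt)
    mat = np.zeros((n // 2, n))
    for k in range(n // 2):
        for m in range(L):
            mat[k, (2 * k + 1 - m) % n] += filt[m]
    return mat


def dwt(x: np.ndarray, mode: str = "symmetric",
        filters: WaveletFilters | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Single-level analysis: returns (approximation, detail)."""
    f = filters or db_filters()
    x = np.asarray(x, dtype=float)
    L = f.length
    if x.ndim != 1:
        raise ValueError("dwt expects a 1-D signal")
    if x.size < 2:
        raise ValueError("signal too short for one decomposition level")
    if mode == "symmetric":
        xp = np.pad(x, (L - 1, L - 1), mode="symmetric")
        cA = np.convolve(xp, f.dec_lo, "valid")[1::2]
        cD = np.convolve(xp, f.dec_hi, "valid")[1::2]
        return cA, cD
    if mode == "periodization":
        if x.size % 2:
            x = np.append(x, x[-1])
        n = x.size
        A = _periodic_analysis_matrix(n, f.dec_lo)
        D = _periodic_analysis_matrix(n, f.dec_hi)
        return A @ x, D @ x
    raise ValueError(f"unknown boundary mode {mode!r}")


def idwt(cA: np.ndarray, cD: np.ndarray, n_out: int, mode: str = "symmetric",
         filters: WaveletFilters | None = None) -> np.ndarray:
    """Single-level synthesis back to ``n_out`` samples."""
    f = filters or db_filters()
    L = f.length
    cA = np.asarray(cA, dtype=float)
    cD = np.asarray(cD, dtype=float)
    if cA.shape != cD.shape:
        raise ValueError("approximation/detail length mismatch")
    if mode == "symmetric":
        m = cA.size
        uA = np.zeros(2 * m)
        uA[::2] = cA
        uD = np.zeros(2 * m)
        uD[::2] = cD
        y = np.convolve(uA, f.rec_lo) + np.convolve(uD, f.rec_hi)
        # constant alignment of the redundant symmetric-extension scheme
        off = L - 2
        if off + n_out > y.size:
            raise ValueError("n_out too large for these coefficients")
        return y[off:off + n_out]
    if mode == "periodization":
        n = 2 * cA.size
        A = _periodic_analysis_matrix(n, f.dec_lo)
        D = _periodic_analysis_matrix(n, f.dec_hi)
        y = A.T @ cA + D.T @ cD  # orthogonal => inverse is transpose
        return y[:n_out]
    raise ValueError(f"unknown boundary mode {mode!r}")


def wavedec(x: np.ndarray, level: int, mode: str = "symmetric",
            filters: WaveletFilters | None = None) -> list[np.ndarray]:
    """Multilevel analysis: ``[cA_level, cD_level, ..., cD_1]``."""
    f = filters or db_filters()
    x = np.asarray(x, dtype=float)
    if level < 1:
        raise ValueError("level must be >= 1")
    if max_level(x.size, f.length) < level:
        raise ValueError(
            f"signal of {x.size} samples too short for a level-{level} "
            f"decomposition with a length-{f.length} filter"
        )
    details = []
    approx = x
    for _ in range(level):
        approx, d = dwt(approx, mode=mode, filters=f)
        details.append(d)
    return [approx] + details[::-1]


def waverec(coeffs: list[np.ndarray], n_out: int, mode: str = "symmetric",
            filters: WaveletFilters | None = None) -> np.ndarray:
    """Inverse of :func:`wavedec`, trimmed to ``n_out`` samples."""
    f = filters or db_filters()
    level = len(coeffs) - 1
    # replay the forward length bookkeeping to trim each synthesis level
    lengths = [n_out]
    for _ in range(level):
        lengths.append(coeff_len(lengths[-1], f.length, mode))
    approx = coeffs[0]
    for i, d in enumerate(coeffs[1:]):
        approx = idwt(approx, d, lengths[level - 1 - i], mode=mode, filters=f)
    return approx
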