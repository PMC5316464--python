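"""Stationary (a trous / undecimated) wavelet transform baseline.

The comparison decomposition: the series is split into approximation and
detail coefficient sequences by circular convolution with Daubechies
analysis filters that are zero-upsampled at each level instead of
decimating the signal, so every coefficient sequence keeps the signal's
length and the transform is shift-covariant.  Reconstruction runs the
cascade backwards by circular correlation with the same filters.  With the
1/sqrt(2) per-level scaling used here the quadrature-mirror identity
|H(f)|^2 + |G(f)|^2 = 1 makes analysis + synthesis exactly inverse on
periodic signals.

The low-frequency component c_L is the reconstruction keeping only the
deepest approximation subband; c_H is the sum of the reconstructed details;
c_L + c_H equals the analyzed series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "FilterBank",
    "SwtCoefficients",
    "SwtComponents",
    "build_filter_bank",
    "pad_to_multiple",
    "swt_decompose",
    "iswt_reconstruct",
    "swt_components",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterBank:
    """Per-level analysis filters (synthesis reuses them by correlation).

    ``low_pass[j]`` / ``high_pass[j]`` are the level-(j+1) filters: the
    level-1 Daubechies pair scaled by 1/sqrt(2), with ``2**j - 1`` zeros
    inserted between adjacent taps at deeper levels.
    """

    wavelet_name: str
    levels: int
    low_pass: tuple[np.ndarray, ...]
    high_pass: tuple[np.ndarray, ...]


@dataclass(frozen=True)
class SwtCoefficients:
    approximations: tuple[np.ndarray, ...]  # a_1 .. a_J
    details: tuple[np.ndarray, ...]         # d_1 .. d_J
    levels: int
    source_length: int


@dataclass(frozen=True)
class SwtComponents:
    c_L: np.ndarray
    c_H: np.ndarray


def _upsample(taps: np.ndarray, gap: int) -> np.ndarray:
    """Insert ``gap`` zeros between adjacent taps (a trous hole insertion)."""
    if gap == 0:
        return taps.copy()
    out = np.zeros(len(taps) + (len(taps) - 1) * gap)
    out[:: gap + 1] = taps
    return out


def build_filter_bank(wavelet_name: str = "db2", levels: int = 1) -> FilterBank:
    """Build the per-level Daubechies analysis filter bank.

    Only the Daubechies family is exposed; other families gave no benefit
    for this decomposition role and are rejected with the supported list.
    """
    supported = pywt.wavelist("db")
    if wavelet_name not in supported:
        raise ValueError(
            f"unsupported wavelet {wavelet_name!r}; supported Daubechies "
            f"names: {', '.join(supported)}"
        )
    if levels < 1:
        raise ValueError("levels must be >= 1")
    w = pywt.Wavelet(wavelet_name)
    base_lo = np.asarray(w.dec_lo) / np.sqrt(2.0)
    base_hi = np.asarray(w.dec_hi) / np.sqrt(2.0)
    low, high = [], []
    for j in range(levels):
        gap = 2**j - 1
        low.append(_upsample(base_lo, gap))
        high.append(_upsample(base_hi, gap))
    return FilterBank(
        wavelet_name=wavelet_name,
        levels=levels,
        low_pass=tuple(low),
        high_pass=tuple(high),
    )


def _circ_conv(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Circular convolution y[n] = sum_i taps[i] * x[n - i]."""
    y = np.zeros_like(x)
    for i in np.flatnonzero(taps):
        y += taps[i] * np.roll(x, i)
    return y


def _circ_corr(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Circular correlation y[n] = sum_i taps[i] * x[n + i]."""
    y = np.zeros_like(x)
    for i in np.flatnonzero(taps):
        y += taps[i] * np.roll(x, -i)
    return y


def pad_to_multiple(x: np.ndarray, multiple: int) -> np.ndarray:
    """Extend by symmetric reflection at the end to the next multiple."""
    x = np.asarray(x, dtype=float)
    rem = x.size % multiple
    if rem == 0:
        return x.copy()
    return np.pad(x, (0, multiple - rem), mode="symmetric")


def swt_decompose(x, bank: FilterBank) -> SwtCoefficients:
    """Undecimated analysis cascade: a_{j+1} = h_j * a_j, d_{j+1} = g_j * a_j.

    Convolution is circular (periodic boundary).  The signal length must be
    an integer multiple of ``2**J``; callers with other lengths should pad
    first (see :func:`pad_to_multiple` / :func:`swt_components`).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("input must be one-dimensional")
    J = bank.levels
    if arr.size % 2**J != 0:
        raise ValueError(
            f"series length {arr.size} is not a multiple of 2**{J} = {2**J}; "
            "pad the series first (pad_to_multiple)"
        )
    approximations, details = [], []
    a = arr
    for j in range(J):
        details.append(_circ_conv(a, bank.high_pass[j]))
        a = _circ_conv(a, bank.low_pass[j])
        approximations.append(a)
    return SwtCoefficients(
        approximations=tuple(approximations),
        details=tuple(details),
        levels=J,
        source_length=arr.size,
    )


def _normalize_keep(keep, levels: int) -> tuple[bool, np.ndarray]:
    if keep is None:
        return False, np.zeros(levels, dtype=bool)
    if isinstance(keep, str):
        if keep == "all":
            return True, np.ones(levels, dtype=bool)
        keep = [keep]
    keep_approx = False
    keep_details = np.zeros(levels, dtype=bool)
    for name in keep:
        if name in ("approx", "a", f"a{levels}"):
            keep_approx = True
        elif name.startswith("d"):
            j = int(name[1:])
            if not 1 <= j <= levels:
                raise ValueError(f"no detail subband {name!r} at depth {levels}")
            keep_details[j - 1] = True
        else:
            raise ValueError(f"unknown subband selector {name!r}")
    return keep_approx, keep_details


def iswt_reconstruct(coeffs: SwtCoefficients, bank: FilterBank, keep="all") -> np.ndarray:
    """Synthesis cascade, optionally zeroing subbands before reconstruction.

    ``keep`` is ``"all"``, ``None`` (nothing), or an iterable of subband
    names among ``"approx"``, ``"d1"`` .. ``"dJ"``.  By linearity, the
    per-subband reconstructions sum to the full reconstruction.
    """
    if coeffs.levels != bank.levels:
        raise ValueError(
            f"coefficient depth {coeffs.levels} does not match filter bank "
            f"depth {bank.levels}"
        )
    keep_approx, keep_details = _normalize_keep(keep, coeffs.levels)
    J = coeffs.levels
    a = coeffs.approximations[-1] if keep_approx else np.zeros(coeffs.source_length)
    for j in range(J - 1, -1, -1):
        d = coeffs.details[j] if keep_details[j] else np.zeros(coeffs.source_length)
        a = _circ_corr(a, bank.low_pass[j]) + _circ_corr(d, bank.high_pass[j])
    return a


def swt_components(x, levels: int = 3, wavelet_name: str = "db2") -> SwtComponents:
    """Low/high-frequency split via SWT (defaults: db2 filters, J = 3).

    Lengths not divisible by ``2**J`` are symmetrically padded, transformed,
    and the components truncated back to the original length; additivity
    ``c_L + c_H == x`` survives the truncation because both components are
    linear in the padded signal.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.size
    bank = build_filter_bank(wavelet_name, levels)
    padded = pad_to_multiple(arr, 2**levels)
    if padded.size != n:
        logger.info(
            "SWT input length %d padded symmetrically to %d (multiple of %d)",
            n, padded.size, 2**levels,
        )
    coeffs = swt_decompose(padded, bank)
    c_L = iswt_reconstruct(coeffs, bank, keep=["approx"])
    c_H = iswt_reconstruct(coeffs, bank, keep=[f"d{j}" for j in range(1, levels + 1)])
    return SwtComponents(c_L=c_L[:n], c_H=c_H[:n])
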