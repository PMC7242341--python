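"""Dyadic wavelet band decomposition of EEG channel signals.

Each channel is split by a multilevel discrete wavelet transform into one
approximation and ``levels`` detail components, and every component is
reconstructed back to the time domain. The result is a set of equal-length
band signals that tile (0, fs/2] dyadically — at fs = 256 Hz with six
levels the nominal bands are 0-2, 2-4, 4-8, 8-16, 16-32, 32-64 and
64-128 Hz, which line up with the clinical delta/theta/alpha/beta/gamma
partition. Because every band is a time-domain signal of the original
length, the same nonlinear measures apply unchanged at every scale; the
multiscale x-axis is the band index, ordered low to high frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 6


@dataclass(frozen=True)
class Band:
    band_id: str            # "A6" (approximation) or "D6".."D1" (details)
    index: int              # 0 = lowest frequency
    low_hz: float
    high_hz: float
    signal: np.ndarray


@dataclass(frozen=True)
class BandSet:
    """Ordered (low -> high frequency) time-domain band signals."""

    bands: tuple[Band, ...]

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def signals(self) -> np.ndarray:
        return np.stack([b.signal for b in self.bands])


def band_frequency_ranges(fs: float, levels: int) -> list[tuple[float, float]]:
    """Nominal dyadic frequency ranges, low to high: (0, fs/2^{L+1}], ..., (fs/4, fs/2]."""
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    edges = [0.0] + [fs / 2 ** (levels + 1 - i) for i in range(levels + 1)]
    return [(edges[i], edges[i + 1]) for i in range(levels + 1)]


def wavelet_band_decompose(
    x: np.ndarray,
    fs: float,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> BandSet:
    """Decompose a signal into ``levels + 1`` time-domain frequency bands.

    The bands are the per-level reconstructions of a multilevel DWT: zeroing
    all coefficient arrays except one and inverting. By linearity the bands
    sum exactly (to float precision) back to the input.

    Raises
    ------
    ValueError
        If the signal is shorter than ``2**levels`` (the error names the
        maximum feasible depth).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if len(x) < 2 ** levels:
        feasible = int(np.log2(len(x))) if len(x) > 1 else 0
        raise ValueError(
            f"signal of length {len(x)} too short for {levels} levels; "
            f"maximum feasible level is {feasible}"
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    ranges = band_frequency_ranges(fs, levels)
    bands = []
    for i in range(levels + 1):
        sel = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
        recon = pywt.waverec(sel, wavelet)[: len(x)]
        band_id = f"A{levels}" if i == 0 else f"D{levels + 1 - i}"
        low, high = ranges[i]
        bands.append(Band(band_id=band_id, index=i, low_hz=low, high_hz=high, signal=recon))
    return BandSet(bands=tuple(bands))
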