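"""Sample entropy and detrended fluctuation analysis.

Sample entropy (SampEn) is the negative natural log of the conditional
probability that two subsequences that match for m points (Chebyshev
distance within r) still match at point m+1, counting distinct pairs only
(no self-matches). Lower values mean more self-similar, more regular
signals. Defaults m = 2, r = 0.2 * SD follow the canonical choices of the
entropy literature.

DFA estimates the scaling exponent alpha of the root-mean-square
fluctuation of the integrated, per-window linearly detrended signal as a
function of window size: alpha = 0.5 for white noise, 1.5 for Brownian
motion, ~1 for 1/f noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampEnConfig:
    """Sample-entropy parameters.

    ``max_samples`` caps the analyzed window (contiguous, centered): the
    pair count is O(N^2) and entropy estimates with m = 2 are stable for a
    few hundred samples and up. ``None`` analyzes the full signal.
    Distance is Chebyshev (maximum coordinate difference), the standard
    choice.
    """

    m: int = 2
    r_factor: float = 0.2
    max_samples: int | None = 1024

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")


@njit(cache=True)
def _sampen_counts(x, m, r):  # pragma: no cover - exercised via wrapper
    n = len(x)
    a = 0  # pairs matching for m+1 points
    b = 0  # pairs matching for m points
    for i in range(n - m):
        for j in range(i + 1, n - m):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(x: np.ndarray, cfg: SampEnConfig = SampEnConfig()) -> float:
    """SampEn(m, r) of a signal in nats; NaN when no template pair matches.

    The tolerance is r = r_factor * SD of the analyzed window. Template
    pairs are counted over the N - m windows whose (m+1)-th continuation
    exists, i < j only, so self-matches never contribute.

    Raises
    ------
    ValueError
        For signals shorter than m + 2 samples or with zero standard
        deviation ("constant signal").
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if cfg.max_samples is not None and len(x) > cfg.max_samples:
        start = (len(x) - cfg.max_samples) // 2
        x = x[start:start + cfg.max_samples]
    if len(x) <= cfg.m + 1:
        raise ValueError(f"signal of length {len(x)} too short for m={cfg.m}")
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("constant signal: sample entropy undefined")
    a, b = _sampen_counts(x, cfg.m, cfg.r_factor * sd)
    if b == 0 or a == 0:
        logger.warning(
            "sample entropy undefined: %s template pairs matched (A=%d, B=%d)",
            "no m-point" if b == 0 else "no (m+1)-point", a, b,
        )
        return float("nan")
    return float(-np.log(a / b))


def dfa_alpha(x: np.ndarray, window_sizes: np.ndarray | None = None) -> float:
    """DFA-1 scaling exponent of a signal.

    The signal is integrated (cumulative sum of deviations from the mean),
    split into non-overlapping windows of each size, linearly detrended per
    window, and the RMS fluctuation F(n) is regressed on window size in
    log-log coordinates; alpha is the least-squares slope.
    """
    x = np.asarray(x, dtype=float)
    if window_sizes is None:
        n_max = len(x) // 4
        if n_max < 4:
            raise ValueError("signal too short for DFA")
        window_sizes = np.unique(
            np.round(np.logspace(np.log10(4), np.log10(n_max), 10)).astype(int)
        )
    window_sizes = np.asarray(window_sizes, dtype=int)
    if len(window_sizes) < 4:
        raise ValueError(f"need at least 4 window sizes, got {len(window_sizes)}")
    if len(x) < 4 * window_sizes.max():
        raise ValueError(
            f"signal of length {len(x)} shorter than 4 * max window "
            f"({4 * window_sizes.max()})"
        )
    profile = np.cumsum(x - x.mean())
    fluct = np.empty(len(window_sizes))
    for idx, n in enumerate(window_sizes):
        k = len(profile) // n
        segs = profile[: k * n].reshape(k, n)
        t = np.arange(n, dtype=float)
        design = np.column_stack([t, np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
        resid = segs.T - design @ coef
        fluct[idx] = np.sqrt(np.mean(resid ** 2))
    slope, _ = np.polyfit(np.log(window_sizes), np.log(fluct), 1)
    return float(slope)
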