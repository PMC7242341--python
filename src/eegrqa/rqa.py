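"""Recurrence quantification analysis: embedding, thresholding, line statistics.

A scalar signal is delay-embedded into phase space (Takens), a recurrence
matrix R[i,j] = 1{ d(x_i, x_j) <= eps } is formed, and the line structures
of R are summarized: diagonal lines measure how long two stretches of
trajectory shadow each other (determinism, Lmax, Lmean), vertical lines
measure how long the system lingers near one state (laminarity, trapping
time TT).

The radius eps is not fixed in signal units but calibrated per signal to a
target recurrence rate (default 10%), which removes amplitude-scale
differences between subjects and frequency bands. Diagonal statistics
exclude a Theiler band of width ``theiler_w`` around the line of identity
(|i - j| < w), suppressing trivial temporal autocorrelation; vertical
statistics use the full matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

_METRICS = {"euclidean": "euclidean", "chebyshev": "chebyshev", "manhattan": "cityblock"}


@dataclass(frozen=True)
class RecurrenceConfig:
    """Parameters of the recurrence analysis.

    ``max_points`` caps the number of embedded points per band signal (a
    contiguous centered window is analyzed); recurrence computations are
    O(N^2), and a few hundred points per band keep a full 19-channel,
    7-band extraction desk-scale. Set to ``None`` to use the full signal.
    """

    m: int = 3
    tau: int = 1
    rr_target: float = 0.10
    norm: str = "euclidean"
    theiler_w: int = 1
    lmin: int = 2
    vmin: int = 2
    max_points: int | None = 400

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be >= 1")
        if not 0 < self.rr_target < 1:
            raise ValueError("rr_target must lie in (0, 1)")
        if self.norm not in _METRICS:
            raise ValueError(f"norm must be one of {sorted(_METRICS)}")
        if self.theiler_w < 0:
            raise ValueError("theiler_w must be >= 0")
        if self.lmin < 2 or self.vmin < 2:
            raise ValueError("lmin and vmin must be >= 2")


@dataclass(frozen=True)
class RQAResult:
    Lmax: float
    Lmean: float   # NaN when no diagonal line >= lmin exists
    TT: float      # NaN when no vertical line >= vmin exists
    DET: float
    LAM: float
    RR: float
    epsilon: float = float("nan")


def embed_time_series(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embed ``x`` into an (N - (m-1)*tau) x m trajectory matrix."""
    x = np.asarray(x, dtype=float)
    n_rows = len(x) - (m - 1) * tau
    if n_rows < 1:
        raise ValueError(
            f"signal of length {len(x)} too short for m={m}, tau={tau}; "
            f"needs at least {(m - 1) * tau + 1} samples"
        )
    return np.column_stack([x[i * tau: i * tau + n_rows] for i in range(m)])


def calibrate_radius(
    traj: np.ndarray, rr_target: float = 0.10, norm: str = "euclidean"
) -> float:
    """Radius eps whose off-diagonal recurrence rate meets ``rr_target``.

    The recurrence rate is a step function of eps, so the search reduces to
    an order statistic: the returned eps is the smallest pairwise distance
    at which the empirical rate first reaches the target (the fixed point a
    bisection on the step function converges to). Deterministic.
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    if traj.shape[0] < 2:
        raise ValueError("need at least 2 trajectory points")
    d = np.sort(pdist(traj, _METRICS[norm]))
    if d[-1] == 0:
        raise ValueError("zero-diameter trajectory: all points identical")
    k = max(1, math.ceil(rr_target * len(d)))
    return float(d[k - 1])


def recurrence_matrix(traj: np.ndarray, epsilon: float, norm: str = "euclidean") -> np.ndarray:
    """Binary symmetric recurrence matrix R[i,j] = 1{ d(i,j) <= eps }."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    dm = squareform(pdist(traj, _METRICS[norm]))
    return dm <= epsilon


@njit(cache=True)
def _diag_run_hist(R, theiler_w):  # pragma: no cover - exercised via wrapper
    n = R.shape[0]
    hist = np.zeros(n + 1, dtype=np.int64)
    for off in range(-(n - 1), n):
        if abs(off) < theiler_w:
            continue
        i0 = max(0, -off)
        j0 = max(0, off)
        length = n - abs(off)
        run = 0
        for t in range(length):
            if R[i0 + t, j0 + t]:
                run += 1
            elif run > 0:
                hist[run] += 1
                run = 0
        if run > 0:
            hist[run] += 1
    return hist


@njit(cache=True)
def _vert_run_hist(R):  # pragma: no cover - exercised via wrapper
    n = R.shape[0]
    hist = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        run = 0
        for i in range(n):
            if R[i, j]:
                run += 1
            elif run > 0:
                hist[run] += 1
                run = 0
        if run > 0:
            hist[run] += 1
    return hist


def _expand(hist: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(len(hist), dtype=np.int64), hist)


def diagonal_line_lengths(R: np.ndarray, theiler_w: int = 1) -> np.ndarray:
    """Maximal diagonal run lengths over all diagonals with |i-j| >= theiler_w.

    ``theiler_w = 1`` excludes exactly the line of identity; ``theiler_w = 0``
    includes it. Each maximal run contributes its length once (a multiset).
    """
    R = _as_binary(R)
    if theiler_w < 0:
        raise ValueError("theiler_w must be >= 0")
    return _expand(_diag_run_hist(R, theiler_w))


def vertical_line_lengths(R: np.ndarray) -> np.ndarray:
    """Maximal vertical run lengths down each column (full matrix)."""
    R = _as_binary(R)
    return _expand(_vert_run_hist(R))


def _as_binary(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square matrix")
    return R.astype(np.bool_)


def rqa_measures(R: np.ndarray, cfg: RecurrenceConfig = RecurrenceConfig()) -> RQAResult:
    """Line-structure statistics of a recurrence matrix.

    Undefined measures (no qualifying line) come back as NaN, never 0 —
    except Lmax, which is 0 by convention when no diagonal of length
    >= lmin exists.
    """
    R = _as_binary(R)
    n = R.shape[0]
    d = diagonal_line_lengths(R, cfg.theiler_w)
    v = vertical_line_lengths(R)
    dq = d[d >= cfg.lmin]
    vq = v[v >= cfg.vmin]

    lmax = float(dq.max()) if dq.size else 0.0
    lmean = float(dq.mean()) if dq.size else float("nan")
    tt = float(vq.mean()) if vq.size else float("nan")
    if not dq.size:
        logger.debug("no diagonal line >= lmin=%d: Lmean undefined", cfg.lmin)
    if not vq.size:
        logger.debug("no vertical line >= vmin=%d: TT undefined", cfg.vmin)

    n_off_theiler = int(d.sum())  # every included recurrence point is in one run
    det = float(dq.sum() / n_off_theiler) if n_off_theiler else float("nan")
    total = int(v.sum())
    lam = float(vq.sum() / total) if total else float("nan")
    off_loi = int(R.sum() - np.trace(R))
    rr = float(off_loi / (n * (n - 1))) if n > 1 else float("nan")
    return RQAResult(Lmax=lmax, Lmean=lmean, TT=tt, DET=det, LAM=lam, RR=rr)


def rqa_from_signal(x: np.ndarray, cfg: RecurrenceConfig = RecurrenceConfig()) -> RQAResult:
    """Embed, calibrate the radius, and quantify a scalar signal in one call.

    Applies the ``max_points`` analysis window (contiguous, centered) before
    embedding. Returns all-NaN measures (Lmax included) for degenerate
    signals whose trajectory has zero diameter.
    """
    x = np.asarray(x, dtype=float)
    if cfg.max_points is not None:
        n_keep = cfg.max_points + (cfg.m - 1) * cfg.tau
        if len(x) > n_keep:
            start = (len(x) - n_keep) // 2
            x = x[start:start + n_keep]
    traj = embed_time_series(x, cfg.m, cfg.tau)
    try:
        eps = calibrate_radius(traj, cfg.rr_target, cfg.norm)
    except ValueError as exc:
        logger.warning("RQA undefined: %s", exc)
        nan = float("nan")
        return RQAResult(nan, nan, nan, nan, nan, nan, nan)
    R = recurrence_matrix(traj, eps, cfg.norm)
    res = rqa_measures(R, cfg)
    return RQAResult(
        Lmax=res.Lmax, Lmean=res.Lmean, TT=res.TT,
        DET=res.DET, LAM=res.LAM, RR=res.RR, epsilon=eps,
    )
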