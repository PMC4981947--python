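"""Mean-shift breakpoint detection via penalized-contrast segmentation.

Phytoplankton abundance series are segmented by least squares: for a
candidate number of segments K, dynamic programming finds the globally
optimal segment boundaries minimising the within-segment sum of squared
deviations J(K). The number of segments is then chosen by Lavielle's
penalized-contrast rule: J is rescaled to [1, Kmax], the discrete second
difference D(K) = J̃(K−1) − 2J̃(K) + J̃(K+1) is computed, and the chosen K
is the largest K whose D(K) exceeds a threshold S (default 0.75); if none
does, K = 1 (no breakpoints). Abundances spanning orders of magnitude are
log-transformed before segmentation by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SegmentationResult",
    "optimal_segmentation",
    "contrast_curve",
    "select_k",
    "detect_breakpoints",
]


class FeasibilityError(ValueError):
    pass


def _segment_cost_tables(y: np.ndarray):
    """Prefix sums so cost(i, j) of segment y[i:j] is O(1)."""
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y ** 2)])

    def cost(i, j):
        n = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / n

    return cost


def _dp(y: np.ndarray, kmax: int, min_seg_len: int):
    """DP over segment ends; returns cost table and backpointers.

    ``d[k][j]`` is the optimal cost of splitting y[0:j] into k segments.
    Ties are broken toward the earliest breakpoint (strict improvement
    required while scanning split points in ascending order).
    """
    n = len(y)
    cost = _segment_cost_tables(y)
    inf = np.inf
    d = np.full((kmax + 1, n + 1), inf)
    back = np.zeros((kmax + 1, n + 1), dtype=int)
    for j in range(min_seg_len, n + 1):
        d[1][j] = cost(0, j)
    for k in range(2, kmax + 1):
        for j in range(k * min_seg_len, n + 1):
            best, arg = inf, -1
            for s in range((k - 1) * min_seg_len, j - min_seg_len + 1):
                v = d[k - 1][s] + cost(s, j)
                if v < best - 1e-12:
                    best, arg = v, s
            d[k][j], back[k][j] = best, arg
    return d, back


def optimal_segmentation(
    y, k: int, min_seg_len: int = 2,
) -> tuple[list[int], float]:
    """Globally optimal K-segment split of ``y`` by least squares.

    Returns (breakpoints, J) where breakpoints are the last indices of the
    first K−1 segments (0-based; segment boundaries in half-open
    convention are at breakpoint+1) and J is the within-segment RSS.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 1 or k > n // min_seg_len:
        raise FeasibilityError(
            f"K={k} infeasible for n={n} with min segment length {min_seg_len}")
    d, back = _dp(y, k, min_seg_len)
    bounds = []
    j = n
    for kk in range(k, 1, -1):
        s = int(back[kk][j])
        bounds.append(s - 1)
        j = s
    return sorted(bounds), float(d[k][n])


def contrast_curve(y, kmax: int, min_seg_len: int = 2) -> np.ndarray:
    """J(K) for K = 1..kmax (non-increasing in K)."""
    y = np.asarray(y, dtype=float)
    if kmax > len(y) // min_seg_len:
        raise FeasibilityError("kmax infeasible for series length")
    d, _ = _dp(y, kmax, min_seg_len)
    return np.array([d[k][len(y)] for k in range(1, kmax + 1)])


def select_k(y, kmax: int = 8, threshold: float = 0.75,
             min_seg_len: int = 2) -> int:
    """Lavielle's penalized-contrast choice of the number of segments.

    J̃ rescales J(K) linearly so J̃(1) = Kmax and J̃(Kmax) = 1; the chosen K
    is the largest K in 2..Kmax−1 with second difference D(K) > threshold,
    else 1.
    """
    y = np.asarray(y, dtype=float)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if len(y) < 2 * min_seg_len:
        raise FeasibilityError("series too short for any breakpoint")
    kmax = min(kmax, len(y) // min_seg_len)
    if kmax < 3:
        # cannot form a second difference; fall back to comparing J(1), J(2)
        j = contrast_curve(y, kmax, min_seg_len)
        return 2 if (kmax == 2 and j[0] > 0 and
                     (j[0] - j[1]) / j[0] > threshold) else 1
    j = contrast_curve(y, kmax, min_seg_len)
    span = j[0] - j[-1]
    if span <= 0 or not np.isfinite(span):
        return 1  # flat contrast: no evidence of any shift
    jt = (j - j[-1]) / span * (kmax - 1) + 1
    best = 1
    for k in range(2, kmax):
        dk = jt[k - 2] - 2 * jt[k - 1] + jt[k]
        if dk > threshold:
            best = k
    return best


@dataclass
class SegmentationResult:
    series_id: str
    k: int
    breakpoints: list[int]             # last index of each non-final segment
    segment_means: list[float]         # on the original (untransformed) scale
    contrast: np.ndarray = field(repr=False)   # J(K), K = 1..kmax
    threshold: float = 0.75
    log_transformed: bool = True


def detect_breakpoints(
    series, variable: str | None = None, kmax: int | None = None,
    threshold: float = 0.75, min_seg_len: int = 2,
    log_transform: bool = True, series_id: str | None = None,
) -> SegmentationResult:
    """Breakpoints of one abundance series.

    Accepts a 1-D array or a DataFrame plus column name. By default the
    series is log(x + floor)-transformed (floor = half the smallest
    positive value) before segmentation, because abundances span orders of
    magnitude; segment means are reported on the original scale.
    """
    if isinstance(series, pd.DataFrame):
        if variable is None or variable not in series.columns:
            raise KeyError(f"variable {variable!r} not in series")
        y_raw = series[variable].to_numpy(dtype=float)
        sid = series_id or variable
    else:
        y_raw = np.asarray(series, dtype=float)
        sid = series_id or (variable or "series")
    if len(y_raw) < 10:
        raise FeasibilityError("need >= 10 samples for breakpoint detection")
    if np.any(~np.isfinite(y_raw)):
        raise ValueError("series contains missing values")

    if log_transform:
        pos = y_raw[y_raw > 0]
        floor = 0.5 * pos.min() if len(pos) else 1.0
        y = np.log(y_raw + floor)
    else:
        y = y_raw.copy()

    kmax_eff = min(kmax or 8, len(y) // 4) if kmax is None else \
        min(kmax, len(y) // min_seg_len)
    kmax_eff = max(kmax_eff, 2)
    k = select_k(y, kmax_eff, threshold, min_seg_len)
    bounds, _ = optimal_segmentation(y, k, min_seg_len)
    j_curve = contrast_curve(y, kmax_eff, min_seg_len)

    edges = [0] + [b + 1 for b in bounds] + [len(y_raw)]
    means = [float(y_raw[lo:hi].mean()) for lo, hi in zip(edges[:-1], edges[1:])]
    return SegmentationResult(
        series_id=sid, k=k, breakpoints=bounds, segment_means=means,
        contrast=j_curve, threshold=threshold, log_transformed=log_transform,
    )
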