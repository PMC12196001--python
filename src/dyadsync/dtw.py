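"""Dynamic Time Warping with the normalized distance index.

The synchrony index of this package is the total DTW distance between two
equally sampled series divided by the combined length of the two series
(N + M).  The recursion is the classic symmetric step pattern with a
double-weighted diagonal ("symmetric2"), whose standard normalization
constant is exactly N + M:

    D(0, 0) = c(0, 0)
    D(i, j) = min( D(i-1, j-1) + 2 c(i, j),
                   D(i-1, j)   +   c(i, j),
                   D(i, j-1)   +   c(i, j) )

with local cost c(i, j) = |x_i - y_j|.  A larger normalized distance means
the two series warp onto each other less well, i.e. lower interpersonal
synchrony.

Two execution paths are provided: :func:`dtw_align` builds the full
cumulative-cost matrix and backtracks a warping path (used for inspection
and in tests), while :func:`batch_normalized_distance` runs a two-row
distance-only kernel over many series pairs at once, which is what the
per-channel, per-block pipeline uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from numba import njit

from .errors import InfeasibleWindowError, ParameterError, ValidationError

#: Finite sentinel for cells outside the window band (avoids inf under fastmath).
_BIG = 1e300

STEP_PATTERNS = ("symmetric2",)


@dataclass(frozen=True)
class Alignment:
    """Result of one DTW alignment.

    ``path`` is an ordered (L, 2) array of 0-based index pairs starting at
    (0, 0) and ending at (N-1, M-1); every step increases at least one
    index by exactly one.  ``normalized_distance = total_distance / (N + M)``.
    """

    total_distance: float
    normalized_distance: float
    path: np.ndarray
    step_pattern: str = "symmetric2"
    window: Optional[int] = None


def _check_series(x: np.ndarray, name: str) -> np.ndarray:
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValidationError(f"{name} must be 1-D, got shape {x.shape}")
    if x.size == 0:
        raise ValidationError(f"{name} is empty")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite values")
    return x


@njit(cache=True, fastmath=True)
def _dtw_total(x, y):  # pragma: no cover - exercised via wrappers
    n = x.shape[0]
    m = y.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = abs(x[0] - y[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        cur[0] = prev[0] + abs(x[i] - y[0])
        xi = x[i]
        for j in range(1, m):
            cij = abs(xi - y[j])
            d = prev[j - 1] + 2.0 * cij
            u = prev[j] + cij
            l = cur[j - 1] + cij
            if u < d:
                d = u
            if l < d:
                d = l
            cur[j] = d
        tmp = prev
        prev = cur
        cur = tmp
    return prev[m - 1]


@njit(cache=True, fastmath=True)
def _dtw_total_batch(X, Y, out):  # pragma: no cover - exercised via wrappers
    # Lane-parallel variant: X (K, n), Y (K, m).  The column recurrence is
    # sequential within a lane but independent across lanes, so the inner
    # loop over lanes vectorizes.
    K, n = X.shape
    m = Y.shape[1]
    prev = np.empty((m, K))
    cur = np.empty((m, K))
    for k in range(K):
        prev[0, k] = abs(X[k, 0] - Y[k, 0])
    for j in range(1, m):
        for k in range(K):
            prev[j, k] = prev[j - 1, k] + abs(X[k, 0] - Y[k, j])
    for i in range(1, n):
        for k in range(K):
            cur[0, k] = prev[0, k] + abs(X[k, i] - Y[k, 0])
        for j in range(1, m):
            for k in range(K):
                cij = abs(X[k, i] - Y[k, j])
                d = prev[j - 1, k] + 2.0 * cij
                u = prev[j, k] + cij
                l = cur[j - 1, k] + cij
                if u < d:
                    d = u
                if l < d:
                    d = l
                cur[j, k] = d
        tmp = prev
        prev = cur
        cur = tmp
    for k in range(K):
        out[k] = prev[m - 1, k]


@njit(cache=True)
def _dtw_matrix(x, y, band):  # pragma: no cover - exercised via wrappers
    # Full cumulative-cost matrix, optionally restricted to |i - j| <= band
    # (band < 0 means no constraint).  Cells outside the band hold _BIG.
    n = x.shape[0]
    m = y.shape[0]
    D = np.full((n, m), _BIG)
    D[0, 0] = abs(x[0] - y[0])
    for j in range(1, m):
        if band >= 0 and j > band:
            break
        D[0, j] = D[0, j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        if band < 0 or i <= band:
            D[i, 0] = D[i - 1, 0] + abs(x[i] - y[0])
        j_lo = 1 if band < 0 else max(1, i - band)
        j_hi = m - 1 if band < 0 else min(m - 1, i + band)
        for j in range(j_lo, j_hi + 1):
            cij = abs(x[i] - y[j])
            d = D[i - 1, j - 1] + 2.0 * cij
            u = D[i - 1, j] + cij
            l = D[i, j - 1] + cij
            if u < d:
                d = u
            if l < d:
                d = l
            D[i, j] = d
    return D


def _backtrack(D: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Recover one optimal warping path, preferring diagonal steps on ties."""
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        cij = abs(x[i] - y[j])
        diag = D[i - 1, j - 1] + 2.0 * cij if (i > 0 and j > 0) else _BIG
        up = D[i - 1, j] + cij if i > 0 else _BIG
        left = D[i, j - 1] + cij if j > 0 else _BIG
        best = min(diag, up, left)
        if diag == best:
            i, j = i - 1, j - 1
        elif up == best:
            i = i - 1
        else:
            j = j - 1
        path.append((i, j))
    return np.asarray(path[::-1], dtype=np.intp)


def dtw_align(
    x: np.ndarray,
    y: np.ndarray,
    step_pattern: str = "symmetric2",
    window: Optional[int] = None,
) -> Alignment:
    """Align two series and return distance, normalized distance and path.

    Parameters
    ----------
    x, y
        Non-empty, finite 1-D series.
    step_pattern
        Only ``"symmetric2"`` is implemented (diagonal steps weighted twice;
        normalization constant N + M).
    window
        Optional Sakoe-Chiba band half-width: the path is restricted to
        ``|i - j| <= window``.
    """
    if step_pattern not in STEP_PATTERNS:
        raise ParameterError(
            f"unsupported step pattern {step_pattern!r}; available: {STEP_PATTERNS}"
        )
    x = _check_series(x, "x")
    y = _check_series(y, "y")
    n, m = x.size, y.size
    if window is not None:
        if window < 0:
            raise ParameterError(f"window must be >= 0, got {window}")
        if abs(n - m) > window:
            raise InfeasibleWindowError(
                f"window {window} < |N - M| = {abs(n - m)}: no warping path exists"
            )
    band = -1 if window is None else int(window)
    D = _dtw_matrix(x, y, band)
    total = float(D[n - 1, m - 1])
    if total >= _BIG:
        raise InfeasibleWindowError(f"window {window} admits no warping path")
    path = _backtrack(D, x, y)
    return Alignment(
        total_distance=total,
        normalized_distance=total / (n + m),
        path=path,
        step_pattern=step_pattern,
        window=window,
    )


def dtw_distance(x: np.ndarray, y: np.ndarray, window: Optional[int] = None) -> float:
    """Total symmetric2 DTW distance (no path recovery)."""
    x = _check_series(x, "x")
    y = _check_series(y, "y")
    if window is not None:
        return dtw_align(x, y, window=window).total_distance
    return float(_dtw_total(x, y))


def normalized_distance(x: np.ndarray, y: np.ndarray, window: Optional[int] = None) -> float:
    """Normalized distance index: total DTW distance / (N + M)."""
    x = _check_series(x, "x")
    y = _check_series(y, "y")
    return dtw_distance(x, y, window=window) / (x.size + y.size)


def batch_normalized_distance(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Normalized distances for K series pairs at once.

    ``X`` and ``Y`` are (K, N) and (K, M) arrays; pair k is ``(X[k], Y[k])``.
    Equivalent to looping :func:`normalized_distance` over the rows, but runs
    the dynamic program across all pairs in one pass.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"X and Y must be 2-D with equal first dimension, got {X.shape} and {Y.shape}"
        )
    if X.shape[1] == 0 or Y.shape[1] == 0:
        raise ValidationError("series must be non-empty")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValidationError("series contain non-finite values")
    out = np.empty(X.shape[0])
    _dtw_total_batch(X, Y, out)
    return out / (X.shape[1] + Y.shape[1])


def normalized_distance_matrix(
    segments_a: Mapping[int, np.ndarray],
    segments_b: Mapping[int, np.ndarray],
    window: Optional[int] = None,
) -> dict[int, float]:
    """Per-channel normalized distances between two subjects' segments.

    Only channels present in both mappings are scored; channels missing in
    either subject are absent from the result (never imputed as zero).
    """
    common = sorted(set(segments_a) & set(segments_b))
    if not common:
        warnings.warn("no common channels between the two subjects", stacklevel=2)
        return {}
    return {
        ch: normalized_distance(segments_a[ch], segments_b[ch], window=window)
        for ch in common
    }
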