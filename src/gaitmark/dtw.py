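"""Dynamic time warping between a gait cycle and a template.

The local cost between frames is the squared Euclidean distance over the
ten IMU channels, c(j, i) = ||x_j - m_i||^2.  The cumulative cost follows
the classic recursion

    D(j, i) = min(D(j-1, i-1), D(j-1, i), D(j, i-1)) + c(j, i)

with D(0, 0) = c(0, 0) and border cells accumulating along their only
predecessor.  No warping-window or slope constraint is applied.  Because
gait-cycle lengths vary, threshold comparisons elsewhere in the package
use the *normalized* cost — cumulative cost divided by the warping-path
length — so that costs are comparable across cycles; the raw cumulative
cost is also exposed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco(*a) if a and callable(a[0]) else deco


@dataclasses.dataclass
class DtwResult:
    """Alignment of a query sequence X (length J) to a template M (length I).

    ``path`` is a (K, 2) integer array of 0-based (j, i) pairs from (0, 0)
    to (J-1, I-1); each step increments j, i or both by one.
    ``normalized_cost`` is ``cumulative_cost / K``.
    """

    cumulative_cost: float
    normalized_cost: float
    path: np.ndarray


def local_cost_matrix(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Squared-Euclidean cost matrix, shape (J, I)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if X.shape[0] == 0 or M.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    if X.shape[1] != M.shape[1]:
        raise ValueError(
            f"channel mismatch: {X.shape[1]} vs {M.shape[1]}")
    return cdist(X, M, metric="sqeuclidean")


@njit(cache=False)
def _cumulative(C):  # pragma: no cover - exercised via dtw_align
    J, I = C.shape
    D = np.empty((J, I))
    D[0, 0] = C[0, 0]
    for i in range(1, I):
        D[0, i] = D[0, i - 1] + C[0, i]
    for j in range(1, J):
        D[j, 0] = D[j - 1, 0] + C[j, 0]
        for i in range(1, I):
            m = D[j - 1, i - 1]
            if D[j - 1, i] < m:
                m = D[j - 1, i]
            if D[j, i - 1] < m:
                m = D[j, i - 1]
            D[j, i] = m + C[j, i]
    return D


def _cumulative_py(C: np.ndarray) -> np.ndarray:
    J, I = C.shape
    D = np.empty((J, I))
    D[0, :] = np.cumsum(C[0, :])
    D[:, 0] = np.cumsum(C[:, 0])
    for j in range(1, J):
        for i in range(1, I):
            D[j, i] = min(D[j - 1, i - 1], D[j - 1, i], D[j, i - 1]) + C[j, i]
    return D


def cumulative_cost_matrix(C: np.ndarray) -> np.ndarray:
    """Full DP table D for a given local cost matrix."""
    C = np.ascontiguousarray(C, dtype=float)
    if _HAVE_NUMBA:
        return _cumulative(C)
    return _cumulative_py(C)


def _backtrack(D: np.ndarray) -> np.ndarray:
    """Optimal path by backtracking; ties prefer diagonal, then (j-1, i)."""
    j, i = D.shape[0] - 1, D.shape[1] - 1
    path = [(j, i)]
    while j > 0 or i > 0:
        if j == 0:
            i -= 1
        elif i == 0:
            j -= 1
        else:
            diag, up, left = D[j - 1, i - 1], D[j - 1, i], D[j, i - 1]
            best = min(diag, up, left)
            if diag == best:
                j, i = j - 1, i - 1
            elif up == best:
                j -= 1
            else:
                i -= 1
        path.append((j, i))
    return np.array(path[::-1], dtype=int)


def dtw_align(X: np.ndarray, M: np.ndarray) -> DtwResult:
    """Align X to M and return cumulative cost, normalized cost and path."""
    C = local_cost_matrix(X, M)
    D = cumulative_cost_matrix(C)
    path = _backtrack(D)
    cum = float(D[-1, -1])
    return DtwResult(cumulative_cost=cum,
                     normalized_cost=cum / len(path),
                     path=path)


def dtw_cost(X: np.ndarray, M: np.ndarray) -> tuple[float, float]:
    """(cumulative, normalized) DTW cost without materializing the path.

    The path length for normalization is still that of the backtracked
    optimal path, so this equals :func:`dtw_align` on both numbers.
    """
    r = dtw_align(X, M)
    return r.cumulative_cost, r.normalized_cost
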