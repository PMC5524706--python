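"""Fixed-radius neighbour counting for density-dependent competition.

Counts, for every point, the number of *other* points within Euclidean
distance <= r (boundary inclusive).  Three equivalent backends: an O(n^2)
vectorised brute force for small n, a numba cell-list for large n, and a
scipy cKDTree fallback when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

_BRUTE_MAX = 3000


def _counts_brute(x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    within = dx * dx + dy * dy <= r * r
    return within.sum(axis=1).astype(np.int64) - 1  # subtract self


if _HAVE_NUMBA:

    @njit(cache=True)
    def _counts_celllist(x, y, r):  # pragma: no cover - compiled
        n = x.size
        out = np.zeros(n, np.int64)
        if n == 0:
            return out
        x0 = x.min()
        y0 = y.min()
        inv = 1.0 / r
        cx = np.empty(n, np.int64)
        cy = np.empty(n, np.int64)
        for i in range(n):
            cx[i] = np.int64((x[i] - x0) * inv)
            cy[i] = np.int64((y[i] - y0) * inv)
        ncy = cy.max() + 1
        key = cx * ncy + cy
        order = np.argsort(key)
        ks = key[order]
        r2 = r * r
        for i in range(n):
            xi = x[i]
            yi = y[i]
            c = 0
            for dxc in range(-1, 2):
                gx = cx[i] + dxc
                if gx < 0:
                    continue
                for dyc in range(-1, 2):
                    gy = cy[i] + dyc
                    if gy < 0 or gy >= ncy:
                        continue
                    k = gx * ncy + gy
                    lo = np.searchsorted(ks, k)
                    hi = np.searchsorted(ks, k + 1)
                    for t in range(lo, hi):
                        j = order[t]
                        ddx = x[j] - xi
                        ddy = y[j] - yi
                        if ddx * ddx + ddy * ddy <= r2 and j != i:
                            c += 1
            out[i] = c
        return out


def _counts_kdtree(x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    from scipy.spatial import cKDTree

    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r, return_length=True)
    return np.asarray(counts, dtype=np.int64) - 1


def crowding_counts(x_km, y_km, r_km: float) -> np.ndarray:
    """Number of other points within ``r_km`` of each point (inclusive)."""
    if r_km <= 0:
        raise ValueError("radius must be positive")
    x = np.ascontiguousarray(x_km, dtype=np.float64)
    y = np.ascontiguousarray(y_km, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size <= _BRUTE_MAX:
        if x.size == 0:
            return np.zeros(0, dtype=np.int64)
        return _counts_brute(x, y, r_km)
    if _HAVE_NUMBA:
        return _counts_celllist(x, y, r_km)
    return _counts_kdtree(x, y, r_km)
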