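"""Penalized exact change-point search (PELT) with a Gaussian cost.

The segment cost is the maximized Gaussian negative log-likelihood up to
constants, ``n * log(sigma2_hat)``, which is sensitive to changes in both
mean and variance.  Empty-variance segments are guarded by a floor tied to
the global variance of the series so that noiseless step traces do not
produce degenerate ``-inf`` costs.

The dynamic program is exact (Killick-style pruning never discards an
optimal candidate for this cost family) and is compiled with numba; the
pure-Python wrapper handles penalties, floors and input checking.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pelt_gaussian", "segment_cost", "brute_force_segmentation"]


@njit(cache=False)
def _pelt_core(x, penalty, min_size, var_floor):  # pragma: no cover - numba
    n = x.shape[0]
    s1 = np.empty(n + 1)
    s2 = np.empty(n + 1)
    s1[0] = 0.0
    s2[0] = 0.0
    for i in range(n):
        s1[i + 1] = s1[i] + x[i]
        s2[i + 1] = s2[i] + x[i] * x[i]

    F = np.empty(n + 1)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=np.int64)
    cand = np.empty(n + 1, dtype=np.int64)
    cand[0] = 0
    ncand = 1

    for t in range(min_size, n + 1):
        best = np.inf
        argbest = 0
        for ci in range(ncand):
            s = cand[ci]
            m = t - s
            if m < min_size:
                continue
            mu = (s1[t] - s1[s]) / m
            v = (s2[t] - s2[s]) / m - mu * mu
            if v < var_floor:
                v = var_floor
            c = F[s] + m * np.log(v) + penalty
            if c < best:
                best = c
                argbest = s
        F[t] = best
        last[t] = argbest
        # prune candidates that can never be optimal again (K = 0 holds for
        # the Gaussian likelihood cost, floor included)
        k = 0
        for ci in range(ncand):
            s = cand[ci]
            m = t - s
            if m < min_size:
                cand[k] = s
                k += 1
                continue
            mu = (s1[t] - s1[s]) / m
            v = (s2[t] - s2[s]) / m - mu * mu
            if v < var_floor:
                v = var_floor
            if F[s] + m * np.log(v) <= F[t]:
                cand[k] = s
                k += 1
        cand[k] = t
        ncand = k + 1

    # backtrack
    breaks = np.empty(n + 1, dtype=np.int64)
    nb = 0
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            breaks[nb] = s
            nb += 1
        t = s
    return breaks[:nb][::-1].copy()


def _var_floor(x: np.ndarray) -> float:
    gv = float(np.var(x))
    return max(gv * 1e-6, 1e-12)


def segment_cost(x: np.ndarray, var_floor: float | None = None) -> float:
    """Gaussian mean+variance cost of one segment, ``n * log(var)``."""
    x = np.asarray(x, dtype=np.float64)
    if var_floor is None:
        var_floor = 1e-12
    v = max(float(np.var(x)), var_floor)
    return x.size * float(np.log(v))


def pelt_gaussian(
    x: np.ndarray,
    penalty: float,
    min_size: int = 5,
    var_floor: float | None = None,
) -> np.ndarray:
    """Optimal change points of ``x`` under the penalized Gaussian cost.

    Returns the sorted internal break indices (each index ``b`` starts a new
    segment ``[b, next_b)``); an empty array means the series is judged
    homogeneous.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series with at least 2 samples")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if min_size < 2:
        raise ValueError("min_size must be >= 2 (single-sample variance is degenerate)")
    if var_floor is None:
        var_floor = _var_floor(x)
    if x.size < 2 * min_size:
        return np.empty(0, dtype=np.int64)
    return _pelt_core(x, float(penalty), int(min_size), float(var_floor))


def brute_force_segmentation(
    x: np.ndarray,
    penalty: float,
    max_breaks: int = 2,
    min_size: int = 5,
    var_floor: float | None = None,
) -> tuple[list[int], float]:
    """Exhaustive search over all segmentations with up to ``max_breaks``.

    Independent reference for small inputs: enumerates every admissible
    break placement and minimizes the identical penalized cost.  Intended
    for series of a few hundred samples at most.
    """
    from itertools import combinations

    x = np.asarray(x, dtype=np.float64)
    if var_floor is None:
        var_floor = _var_floor(x)
    n = x.size

    def total(breaks: tuple[int, ...]) -> float:
        bounds = (0, *breaks, n)
        c = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < min_size:
                return np.inf
            c += segment_cost(x[a:b], var_floor) + penalty
        return c

    best: tuple[float, tuple[int, ...]] = (total(()), ())
    positions = range(1, n)
    for k in range(1, max_breaks + 1):
        for combo in combinations(positions, k):
            c = total(combo)
            if c < best[0]:
                best = (c, combo)
    return list(best[1]), best[0]
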