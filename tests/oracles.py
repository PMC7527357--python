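"""Independent brute-force oracles used to cross-check the estimators.

These deliberately avoid the package's code paths: weighted regressions are
solved from explicitly accumulated normal equations, the BH adjustment is the
textbook step-up written as loops, and the weighted median is an exhaustive
cumulative-weight scan.
"""

from __future__ import annotations

import numpy as np


def wls_through_origin(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted regression through the origin: slope and fixed-effect SE."""
    sxx = float(np.sum(w * x * x))
    sxy = float(np.sum(w * x * y))
    return sxy / sxx, sxx**-0.5


def wls_with_intercept(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float, float, float]:
    """Weighted simple regression: (intercept, slope, se_int, se_slope).

    SEs carry the multiplicative overdispersion max(1, Q_res/(n-2)).
    """
    s0 = float(np.sum(w))
    s1 = float(np.sum(w * x))
    s2 = float(np.sum(w * x * x))
    sy = float(np.sum(w * y))
    sxy = float(np.sum(w * x * y))
    det = s0 * s2 - s1 * s1
    intercept = (s2 * sy - s1 * sxy) / det
    slope = (s0 * sxy - s1 * sy) / det
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    n = len(x)
    phi = max(1.0, q / (n - 2))
    se_int = np.sqrt(phi * s2 / det)
    se_slope = np.sqrt(phi * s0 / det)
    return intercept, slope, se_int, se_slope


def wls_two_covariates_no_intercept(
    x1: np.ndarray, x2: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float, float, float]:
    """Bivariate weighted regression through the origin: (b1, b2, se1, se2)."""
    a11 = float(np.sum(w * x1 * x1))
    a12 = float(np.sum(w * x1 * x2))
    a22 = float(np.sum(w * x2 * x2))
    c1 = float(np.sum(w * x1 * y))
    c2 = float(np.sum(w * x2 * y))
    det = a11 * a22 - a12 * a12
    b1 = (a22 * c1 - a12 * c2) / det
    b2 = (a11 * c2 - a12 * c1) / det
    resid = y - b1 * x1 - b2 * x2
    q = float(np.sum(w * resid**2))
    n = len(y)
    phi = max(1.0, q / (n - 2))
    se1 = np.sqrt(phi * a22 / det)
    se2 = np.sqrt(phi * a11 / det)
    return b1, b2, se1, se2


def weighted_median_scan(theta, weights) -> float:
    """Exhaustive cumulative-weight scan for the interpolated weighted median."""
    pairs = sorted(zip(list(theta), list(weights)))
    total = sum(w for _, w in pairs)
    running = 0.0
    points = []
    for t, w in pairs:
        mid = (running + w / 2.0) / total
        points.append((mid, t))
        running += w
    if 0.5 <= points[0][0]:
        return points[0][1]
    if 0.5 >= points[-1][0]:
        return points[-1][1]
    for (p0, t0), (p1, t1) in zip(points, points[1:]):
        if p0 <= 0.5 <= p1:
            if p1 == p0:
                return t0
            return t0 + (t1 - t0) * (0.5 - p0) / (p1 - p0)
    raise AssertionError("unreachable")


def bh_step_up(pvalues) -> list[float]:
    """Textbook Benjamini–Hochberg step-up adjusted p-values, original order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted_sorted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        q = min(1.0, pvalues[i] * m / rank)
        running_min = min(running_min, q)
        adjusted_sorted[rank - 1] = running_min
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adjusted_sorted[rank]
    return out
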