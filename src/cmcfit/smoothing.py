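"""Local-quadratic (Savitzky-Golay-like) smoothing on possibly uneven grids.

A quadratic is least-squares fitted in a sliding window around every grid
point; its coefficients give smoothed values and first/second derivatives.
Unlike a classical Savitzky-Golay filter this works on non-uniform grids
(logarithmic concentration spacing is common for fluorescence titrations).
"""

from __future__ import annotations

import numpy as np

__all__ = ["local_quadratic_derivatives", "quadratic_refine"]


def window_size(n: int, frac: float, minimum: int = 5) -> int:
    """Window length: ``frac`` of the points, at least ``minimum``, at most n."""
    return min(n, max(minimum, int(round(frac * n))))


def local_quadratic_derivatives(
    x: np.ndarray, y: np.ndarray, frac: float = 0.2, minimum: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed value, first and second derivative of y(x) at each grid point.

    Returns ``(y_smooth, dy, d2y)``.  The window is clamped at the edges so
    every point uses exactly ``window`` neighbours.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 points for local-quadratic smoothing")
    w = window_size(n, frac, minimum)
    half = w // 2
    ys = np.empty(n)
    d1 = np.empty(n)
    d2 = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - w))
        sl = slice(lo, lo + w)
        u = x[sl] - x[i]
        # polyfit in centred coordinates: y ~ c2 u^2 + c1 u + c0
        c2, c1, c0 = np.polyfit(u, y[sl], 2)
        ys[i] = c0
        d1[i] = c1
        d2[i] = 2.0 * c2
    return ys, d1, d2


def quadratic_refine(x: np.ndarray, v: np.ndarray, i: int) -> float:
    """Refine the extremum of v near grid index i by a parabola through 3 points.

    Falls back to x[i] when i is at a boundary or the parabola degenerates.
    """
    if i <= 0 or i >= len(x) - 1:
        return float(x[i])
    c = np.polyfit(x[i - 1 : i + 2] - x[i], v[i - 1 : i + 2], 2)
    if c[0] == 0:
        return float(x[i])
    xv = -c[1] / (2.0 * c[0]) + x[i]
    # keep the refinement inside the bracketing interval
    if not (x[i - 1] <= xv <= x[i + 1]):
        return float(x[i])
    return float(xv)
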