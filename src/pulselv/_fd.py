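"""Fourth-order finite differences on uniform grids."""

from __future__ import annotations

import numpy as np


def deriv1(y: np.ndarray, h: float) -> np.ndarray:
    """First derivative, 4th-order central stencil, one-sided at the ends."""
    y = np.asarray(y, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 nodes for 4th-order differences")
    d = np.empty_like(y)
    d[2:-2] = (y[:-4] - 8.0 * y[1:-3] + 8.0 * y[3:-1] - y[4:]) / (12.0 * h)
    d[0] = (-25.0 * y[0] + 48.0 * y[1] - 36.0 * y[2]
            + 16.0 * y[3] - 3.0 * y[4]) / (12.0 * h)
    d[1] = (-3.0 * y[0] - 10.0 * y[1] + 18.0 * y[2]
            - 6.0 * y[3] + y[4]) / (12.0 * h)
    d[-2] = (3.0 * y[-1] + 10.0 * y[-2] - 18.0 * y[-3]
             + 6.0 * y[-4] - y[-5]) / (12.0 * h)
    d[-1] = (25.0 * y[-1] - 48.0 * y[-2] + 36.0 * y[-3]
             - 16.0 * y[-4] + 3.0 * y[-5]) / (12.0 * h)
    return d


def deriv(y: np.ndarray, h: float, order: int) -> np.ndarray:
    """n-th derivative by repeated 4th-order first differences."""
    if order < 1:
        raise ValueError("order must be >= 1")
    out = np.asarray(y, dtype=float)
    for _ in range(order):
        out = deriv1(out, h)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            "finite-difference derivative produced non-finite values; "
            "use a denser grid")
    return out
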