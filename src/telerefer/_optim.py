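"""Grid-plus-golden-section maximization of (piecewise-smooth) unimodal profiles."""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)


def count_local_maxima(values: np.ndarray, tol: float = 1e-9) -> int:
    """Number of local maxima of a sampled profile, ignoring sub-``tol`` wiggles.

    Runs of near-equal values are merged; a flat profile counts as one
    (degenerate) maximum.
    """
    v = np.asarray(values, dtype=float)
    dv = np.diff(v)
    sign = np.where(dv > tol, 1, np.where(dv < -tol, -1, 0))
    sign = sign[sign != 0]
    if len(sign) == 0:
        return 1
    switches = int(np.sum((sign[:-1] > 0) & (sign[1:] < 0)))
    n = switches
    if sign[0] < 0:
        n += 1  # boundary maximum at the left edge
    if sign[-1] > 0:
        n += 1  # boundary maximum at the right edge
    return max(1, n)


def maximize_on_interval(
    profit: Callable[[float], float],
    lo: float,
    hi: float,
    grid_n: int = 2001,
    xatol: float = 1e-7,
) -> tuple[float, float, dict]:
    """Maximize ``profit`` on [lo, hi]: coarse grid argmax + bounded golden refinement.

    Ties (a flat or plateaued objective) break toward the smallest maximizer.
    Returns ``(x_star, profit(x_star), info)`` where ``info`` reports whether
    the sampled profile looked unimodal.
    """
    xs = np.linspace(lo, hi, grid_n)
    vals = np.array([profit(float(x)) for x in xs])
    vmax = vals.max()
    scale = max(1.0, abs(vmax))
    if vmax - vals.min() <= 1e-12 * scale:
        # flat objective: smallest grid point by convention
        return float(xs[0]), float(vals[0]), {"unimodal": True, "flat": True}

    n_max = count_local_maxima(vals)
    if n_max > 1:
        log.warning("profit profile has %d local maxima on the grid; using global argmax", n_max)

    i = int(np.argmax(vals))  # np.argmax returns the first (smallest-x) maximizer
    a = float(xs[max(i - 1, 0)])
    b = float(xs[min(i + 1, grid_n - 1)])
    res = minimize_scalar(lambda x: -profit(float(x)), bounds=(a, b), method="bounded",
                          options={"xatol": xatol})
    x_star, v_star = float(xs[i]), float(vals[i])
    if res.success and -res.fun >= v_star:
        x_star, v_star = float(res.x), float(-res.fun)
    return x_star, v_star, {"unimodal": n_max <= 1, "flat": False, "n_local_maxima": n_max}
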