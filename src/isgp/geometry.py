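"""Circle-circle intersection ("lens") area and its inverse.

Two disks of equal radius ``r`` whose centers are a distance ``d`` apart
overlap in a lens-shaped region of area

    A(d) = 2 r^2 arccos(d / 2r) - (d / 2) sqrt(4 r^2 - d^2),

a continuous, strictly decreasing bijection from [0, 2r] onto [0, pi r^2].
Because the map is bijective, an (estimated) overlap area determines a
unique center distance, which is the analytic core of distance recovery
from grid-point set overlap: invert A at the estimated area.

The Monte-Carlo oracle here exists purely as an independent cross-check of
the closed form; production code never calls it.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

__all__ = ["lens_area", "invert_lens_area", "mc_lens_area_oracle", "MCArea"]

#: Absolute root tolerance for the area inversion (meters).
INVERSION_TOL = 1e-9

#: Relative slack on the admissible area range [0, pi r^2]; estimated areas
#: within this margin outside the range are snapped to the boundary, since
#: rounded Dice coefficients can push an estimate marginally out of range.
AREA_SLACK = 1e-9


def _check_radius(r: float) -> float:
    r = float(r)
    if not math.isfinite(r) or r <= 0.0:
        raise ValueError(f"radius must be finite and > 0, got {r}")
    return r


def lens_area(d: float, r: float) -> float:
    """Area of intersection of two radius-``r`` disks with centers ``d`` apart.

    Parameters
    ----------
    d : float
        Center-to-center distance, meters; must lie in ``[0, 2r]``.
    r : float
        Common disk radius, meters, strictly positive.

    Returns
    -------
    float
        Lens area in square meters, in ``[0, pi r^2]``.

    Raises
    ------
    ValueError
        If ``d`` is negative or exceeds ``2r`` (disks with ``d > 2r`` are
        disjoint; callers must censor such pairs rather than evaluate here).
    """
    r = _check_radius(r)
    d = float(d)
    if d < 0.0 or d > 2.0 * r:
        raise ValueError(f"d must lie in [0, 2r] = [0, {2 * r}], got {d}")
    # Clamp absorbs floating-point overshoot of d/(2r) at the d = 2r endpoint.
    cos_arg = min(1.0, max(-1.0, d / (2.0 * r)))
    # With theta = arccos(d/2r) the area is 2 r^2 (theta - sin(2 theta)/2).
    # Near d = 2r the two terms cancel catastrophically, so a small-angle
    # series keeps full relative precision (and the area nonnegative).
    theta = math.acos(cos_arg)
    if theta < 1e-3:
        g = (2.0 / 3.0) * theta**3 - (2.0 / 15.0) * theta**5 \
            + (4.0 / 315.0) * theta**7
    else:
        g = theta - 0.5 * math.sin(2.0 * theta)
    return max(0.0, 2.0 * r * r * g)


def invert_lens_area(a_hat: float, r: float) -> float:
    """Unique center distance ``d`` in ``[0, 2r]`` with ``lens_area(d, r) == a_hat``.

    The lens area is strictly decreasing in ``d``, so the root is unique and
    bracketed by ``[0, 2r]``; Brent's method finds it to absolute tolerance
    1e-9. Exact endpoints are returned without iteration: a full-overlap
    area maps to 0, a zero area to ``2r``. Areas outside ``[0, pi r^2]`` by
    at most ``1e-9 * pi r^2`` are snapped to the nearest boundary.
    """
    r = _check_radius(r)
    a_hat = float(a_hat)
    a_max = math.pi * r * r
    slack = AREA_SLACK * a_max
    if a_hat < -slack or a_hat > a_max + slack:
        raise ValueError(f"estimated area {a_hat} outside [0, {a_max}]")
    a_hat = min(a_max, max(0.0, a_hat))
    if a_hat == 0.0:
        return 2.0 * r
    if a_hat == a_max:
        return 0.0
    return brentq(lambda d: lens_area(d, r) - a_hat, 0.0, 2.0 * r, xtol=INVERSION_TOL)


class MCArea(NamedTuple):
    """Monte-Carlo area estimate with its standard error (square meters)."""

    area: float
    stderr: float


def mc_lens_area_oracle(d: float, r: float, n_samples: int, seed: int) -> MCArea:
    """Rejection-sampling estimate of the lens area, for testing the closed form.

    Samples points uniformly in the first disk and counts the fraction that
    also falls in the second; the lens area is that fraction times
    ``pi r^2``. The binomial standard error accompanies the estimate so
    agreement tests can be phrased in standard-error units.
    """
    r = _check_radius(r)
    d = float(d)
    if d < 0.0 or d > 2.0 * r:
        raise ValueError(f"d must lie in [0, 2r], got {d}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    disk_area = math.pi * r * r
    # Uniform sample in the disk centered at the origin via polar inversion.
    u = rng.random(n_samples)
    theta = rng.random(n_samples) * (2.0 * math.pi)
    rad = r * np.sqrt(u)
    x = rad * np.cos(theta)
    y = rad * np.sin(theta)
    # Second disk centered at (d, 0).
    inside = (x - d) ** 2 + y**2 < r * r
    p = inside.mean()
    return MCArea(
        area=p * disk_area,
        stderr=math.sqrt(p * (1.0 - p) / n_samples) * disk_area,
    )
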