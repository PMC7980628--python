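"""Distance recovery from pseudonym overlap.

Given two pseudonyms encoded against the same grid with the same radius,
the Dice coefficient

    s = 2 |G_P ∩ G_Q| / (|G_P| + |G_Q|)

estimates what fraction of a circle's area the two encoding circles share,
so the lens area is estimated as ``A_hat = s * pi * r^2`` and the distance
follows by inverting the lens-area bijection on [0, 2r]. Pairs with empty
intersection are censored: the circles are disjoint, so only "distance is
2r or greater" can be stated.

The relative error reported throughout divides by the *approximated*
distance, ``(d_true - d_hat) / d_hat``; pass ``denominator="true"`` for the
conventional variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .encoder import Pseudonym
from .geometry import invert_lens_area

__all__ = [
    "SimilarityResult",
    "DistanceEstimate",
    "dice",
    "estimate_area",
    "estimate_distance",
    "relative_error",
]


@dataclass(frozen=True)
class SimilarityResult:
    """Dice coefficient with the underlying set sizes."""

    s: float
    intersection_size: int
    size_p: int
    size_q: int


@dataclass(frozen=True)
class DistanceEstimate:
    """Approximate distance between two pseudonymized locations.

    ``censored`` is True exactly when the label intersection is empty, in
    which case ``d_hat`` is ``2r`` (a lower bound, not an estimate) and
    should be read as "distance >= 2r".
    """

    id_p: str
    id_q: str
    d_hat: float
    censored: bool
    s: float
    a_hat: float
    r: float


def _check_comparable(p: Pseudonym, q: Pseudonym) -> None:
    if p.r != q.r:
        raise ValueError(f"radius mismatch: {p.r} vs {q.r}; sets are incomparable")
    if p.grid_fingerprint != q.grid_fingerprint:
        raise ValueError(
            "grid fingerprint mismatch: pseudonyms were encoded against "
            "different grids and cannot be compared"
        )


def dice(p: Pseudonym, q: Pseudonym) -> SimilarityResult:
    """Dice set-overlap similarity of two comparable pseudonyms."""
    _check_comparable(p, q)
    inter = len(p.labels & q.labels)
    denom = len(p.labels) + len(q.labels)
    if denom == 0:
        raise ValueError("both pseudonyms are empty")
    return SimilarityResult(
        s=2.0 * inter / denom,
        intersection_size=inter,
        size_p=len(p.labels),
        size_q=len(q.labels),
    )


def estimate_area(s: float, r: float) -> float:
    """Lens-area estimate ``A_hat = s * pi * r^2`` from a Dice coefficient."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"Dice coefficient must lie in [0, 1], got {s}")
    if r <= 0:
        raise ValueError("r must be > 0")
    return s * math.pi * r * r


def estimate_distance(p: Pseudonym, q: Pseudonym) -> DistanceEstimate:
    """Approximate the distance between two pseudonymized locations.

    Symmetric in its arguments. An empty label intersection yields a
    censored estimate (true distance >= 2r); otherwise the Dice coefficient
    is converted to an area and the lens-area formula inverted.
    """
    sim = dice(p, q)
    r = p.r
    if sim.intersection_size == 0:
        return DistanceEstimate(
            id_p=p.id, id_q=q.id, d_hat=2.0 * r, censored=True,
            s=0.0, a_hat=0.0, r=r,
        )
    a_hat = estimate_area(sim.s, r)
    d_hat = invert_lens_area(a_hat, r)
    return DistanceEstimate(
        id_p=p.id, id_q=q.id, d_hat=d_hat, censored=False,
        s=sim.s, a_hat=a_hat, r=r,
    )


def relative_error(
    d_true: float,
    est: DistanceEstimate,
    denominator: Literal["estimated", "true"] = "estimated",
) -> float:
    """Signed relative error of a distance estimate.

    Default convention divides by the approximated distance:
    ``(d_true - d_hat) / d_hat``. Undefined for censored estimates.
    """
    if est.censored:
        raise ValueError(
            f"relative error undefined for censored pair ({est.id_p}, {est.id_q})"
        )
    if d_true <= 0:
        raise ValueError("d_true must be > 0")
    if est.d_hat == 0.0 and denominator == "estimated":
        raise ValueError(
            "relative error undefined: estimated distance is 0 "
            "(identical label sets); use denominator='true' if needed"
        )
    if denominator == "estimated":
        return (d_true - est.d_hat) / est.d_hat
    if denominator == "true":
        return (d_true - est.d_hat) / d_true
    raise ValueError(f"unknown denominator convention {denominator!r}")
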