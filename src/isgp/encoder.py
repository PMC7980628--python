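"""Pseudonymization of locations as grid-label sets.

A location ``P`` is replaced by the set of labels of all grid points lying
strictly within radius ``r`` of it. The label set, together with ``r`` and
a grid fingerprint, is the only artifact a data holder releases; it carries
no coordinates. Working areas are enlarged beyond the data's bounding box
so that every radius-``r`` circle is fully covered by grid — circles that
leak past the grid edge contain too few points and both lose precision and
ease re-identification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .grid import BoundingBox, LabeledGrid, points_within

__all__ = [
    "PlanarPoint",
    "Pseudonym",
    "enlarge_bbox",
    "encode",
    "encode_batch",
    "write_pseudonyms",
    "read_pseudonyms",
    "DEFAULT_AREA_FACTOR",
    "MIN_CARDINALITY_WARN",
]

#: Default enlargement of the working area relative to the data bbox,
#: chosen so the computation region dwarfs the data region (~11x), which
#: both covers boundary circles and blurs where the data actually sits.
DEFAULT_AREA_FACTOR = 11.4

#: Below this many grid points per circle, Dice quantization noise starts
#: to dominate the distance estimate; encoding warns but proceeds.
MIN_CARDINALITY_WARN = 30


@dataclass(frozen=True)
class PlanarPoint:
    """An identifier plus projected planar coordinates in meters."""

    id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for point {self.id!r}")


@dataclass(frozen=True)
class Pseudonym:
    """Label set standing in for one location.

    Contains only opaque labels, the encoding radius, and the fingerprint
    of the grid used — never coordinates.
    """

    id: str
    labels: frozenset[str]
    r: float
    grid_fingerprint: str

    @property
    def cardinality(self) -> int:
        return len(self.labels)


def enlarge_bbox(
    points_bbox: BoundingBox,
    target_area_factor: float = DEFAULT_AREA_FACTOR,
    min_buffer: float = 0.0,
) -> BoundingBox:
    """Symmetrically expand a bounding box for grid generation.

    The result (a) has area at least ``target_area_factor`` times the input
    area and (b) keeps every input-box point at least ``min_buffer`` from
    each edge. Callers pass ``min_buffer=r`` so each encoding circle fits
    inside the grid. Expansion is symmetric about the input box center and
    preserves its aspect ratio when scaling for area.
    """
    if target_area_factor < 1:
        raise ValueError("target_area_factor must be >= 1")
    if min_buffer < 0:
        raise ValueError("min_buffer must be >= 0")
    w = points_bbox.width + 2.0 * min_buffer
    h = points_bbox.height + 2.0 * min_buffer
    target_area = target_area_factor * points_bbox.area
    if w * h < target_area:
        s = math.sqrt(target_area / (w * h))
        w *= s
        h *= s
    cx = (points_bbox.xmin + points_bbox.xmax) / 2.0
    cy = (points_bbox.ymin + points_bbox.ymax) / 2.0
    return BoundingBox(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


class EmptyPseudonymError(ValueError):
    """No grid point within r of the location: the encoding carries no
    information. Use a denser grid or a larger radius."""


def encode(
    point: PlanarPoint,
    grid: LabeledGrid,
    r: float,
    min_cardinality_warn: int = MIN_CARDINALITY_WARN,
) -> Pseudonym:
    """Pseudonymize one location against a labeled grid.

    Deterministic given ``(grid, r)``. Warns if the point's radius-``r``
    circle is not fully inside the grid bbox (boundary precision loss) or
    if fewer than ``min_cardinality_warn`` grid points fall in the circle.
    Raises :class:`EmptyPseudonymError` on an empty label set.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    bbox = grid.bbox
    if (
        point.x - r < bbox.xmin
        or point.x + r > bbox.xmax
        or point.y - r < bbox.ymin
        or point.y + r > bbox.ymax
    ):
        warnings.warn(
            f"circle of point {point.id!r} extends beyond the grid bbox; "
            "the encoding loses precision near the boundary",
            stacklevel=2,
        )
    labels = points_within(grid, (point.x, point.y), r)
    if not labels:
        raise EmptyPseudonymError(
            f"point {point.id!r}: no grid point within r={r}; "
            "increase grid density or radius"
        )
    if len(labels) < min_cardinality_warn:
        warnings.warn(
            f"point {point.id!r}: only {len(labels)} grid points in circle; "
            "Dice quantization error may be large",
            stacklevel=2,
        )
    return Pseudonym(
        id=point.id,
        labels=frozenset(labels),
        r=float(r),
        grid_fingerprint=grid.fingerprint,
    )


def encode_batch(
    points: Sequence[PlanarPoint],
    grid: LabeledGrid,
    r: float,
    min_cardinality_warn: int = MIN_CARDINALITY_WARN,
) -> list[Pseudonym]:
    """Elementwise :func:`encode`, preserving input order.

    A per-point failure is re-raised with the offending point id attached.
    """
    out: list[Pseudonym] = []
    for p in points:
        try:
            out.append(encode(p, grid, r, min_cardinality_warn))
        except EmptyPseudonymError:
            raise
        except ValueError as exc:
            raise ValueError(f"point {p.id!r}: {exc}") from exc
    return out


# -- pseudonym file --------------------------------------------------------
# One record per point: id, r, grid fingerprint, sorted label list. This
# file (plus r) is exactly what the analyst receives; it never contains
# coordinates. Labels are sorted for canonical, diff-able output and read
# back with set semantics.


def write_pseudonyms(pseudonyms: Iterable[Pseudonym], path: str | Path) -> None:
    lines = ["id\tr\tgrid_fingerprint\tlabels"]
    for p in pseudonyms:
        labs = " ".join(sorted(p.labels, key=lambda s: (len(s), s)))
        lines.append(f"{p.id}\t{p.r!r}\t{p.grid_fingerprint}\t{labs}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pseudonyms(path: str | Path) -> list[Pseudonym]:
    out: list[Pseudonym] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "id\tr\tgrid_fingerprint\tlabels":
            raise ValueError(f"not a pseudonym file: {path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, r, fp, labs = line.split("\t")
            out.append(
                Pseudonym(
                    id=pid,
                    labels=frozenset(labs.split()),
                    r=float(r),
                    grid_fingerprint=fp,
                )
            )
    return out
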