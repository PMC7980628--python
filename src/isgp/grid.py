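"""Labeled grids: lattices or uniform random point sets with opaque labels.

A grid is the shared secret of the pseudonymization protocol. Two data
holders agree on the same grid (same geometry, same labels) and never show
it to the analyst; each location is then represented by the labels of the
grid points falling strictly within radius ``r`` of it. Labels are either
a seeded random permutation of ``1..n`` or keyed-hash digests of the grid
point index, and are opaque downstream: nothing about a label reveals a
coordinate.
"""

from __future__ import annotations

import hashlib
import hmac
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "BoundingBox",
    "GridSpec",
    "LabeledGrid",
    "make_grid",
    "make_regular_grid",
    "make_random_grid",
    "assign_labels",
    "points_within",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in planar meters."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"degenerate bounding box: {self}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        )

    @classmethod
    def of_points(cls, x: Sequence[float], y: Sequence[float]) -> "BoundingBox":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return cls(float(x.min()), float(y.min()), float(x.max()), float(y.max()))


@dataclass(frozen=True)
class GridSpec:
    """Parameters the parties agree on before generating a grid.

    ``n_points`` is a target: a regular lattice realizes the count that its
    spacing admits inside the box (edge effects), a random grid realizes it
    exactly. ``seed`` drives random placement and label shuffling; ``key``,
    if given, switches labeling to keyed HMAC-SHA256 digests of the point
    index (the key itself is never serialized).
    """

    kind: Literal["regular", "random"]
    n_points: int
    bbox: BoundingBox
    seed: int = 0
    key: bytes | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("regular", "random"):
            raise ValueError(f"kind must be 'regular' or 'random', got {self.kind!r}")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass(frozen=True)
class LabeledGrid:
    """Grid-point coordinates plus one distinct opaque label per point.

    ``fingerprint`` digests the geometry and labels; pseudonyms carry it so
    that sets encoded against different grids are never compared.
    """

    coordinates: np.ndarray  # shape (n, 2), meters
    labels: tuple[str, ...]
    kind: str
    bbox: BoundingBox
    spacing: float | None  # lattice spacing h, regular grids only
    fingerprint: str = ""
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coordinates must have shape (n, 2)")
        if len(self.labels) != len(coords):
            raise ValueError("labels and coordinates must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be pairwise distinct")
        object.__setattr__(self, "coordinates", coords)
        if not self.fingerprint:
            object.__setattr__(self, "fingerprint", _fingerprint(self))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            object.__setattr__(self, "_tree", cKDTree(self.coordinates))
        return self._tree

    # -- serialization -----------------------------------------------------
    # Delimited text: '#'-prefixed header block (kind, bbox, spacing,
    # fingerprint; never the key), then one "label,x,y" row per point.

    def to_file(self, path: str | Path) -> None:
        lines = [
            "# isgp-grid v1",
            f"# kind={self.kind}",
            f"# bbox={self.bbox.xmin!r},{self.bbox.ymin!r},{self.bbox.xmax!r},{self.bbox.ymax!r}",
            f"# spacing={'' if self.spacing is None else repr(self.spacing)}",
            f"# fingerprint={self.fingerprint}",
            "label,x,y",
        ]
        for lab, (x, y) in zip(self.labels, self.coordinates):
            lines.append(f"{lab},{float(x)!r},{float(y)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "LabeledGrid":
        header: dict[str, str] = {}
        labels: list[str] = []
        rows: list[tuple[float, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line == "label,x,y":
                    continue
                if line.startswith("#"):
                    body = line.lstrip("# ")
                    if "=" in body:
                        k, v = body.split("=", 1)
                        header[k] = v
                    continue
                lab, x, y = line.split(",")
                labels.append(lab)
                rows.append((float(x), float(y)))
        xmin, ymin, xmax, ymax = (float(v) for v in header["bbox"].split(","))
        spacing = float(header["spacing"]) if header.get("spacing") else None
        grid = cls(
            coordinates=np.array(rows),
            labels=tuple(labels),
            kind=header["kind"],
            bbox=BoundingBox(xmin, ymin, xmax, ymax),
            spacing=spacing,
            fingerprint=header["fingerprint"],
        )
        return grid


def _fingerprint(grid: LabeledGrid) -> str:
    h = hashlib.sha256()
    h.update(grid.kind.encode())
    h.update(
        np.array(
            [grid.bbox.xmin, grid.bbox.ymin, grid.bbox.xmax, grid.bbox.ymax]
        ).tobytes()
    )
    h.update(np.ascontiguousarray(grid.coordinates).tobytes())
    for lab in grid.labels:
        h.update(lab.encode())
    return h.hexdigest()[:16]


def make_regular_grid(spec: GridSpec) -> LabeledGrid:
    """Cell-centered rectangular lattice approximating ``spec.n_points``.

    Spacing ``h = sqrt(bbox_area / n_points)``; points sit at cell centers
    ``(xmin + h/2 + i*h, ymin + h/2 + j*h)``, so none lies on the boundary.
    The realized count can differ from the target by edge effects and is
    simply ``len(grid)``.
    """
    if spec.kind != "regular":
        raise ValueError("make_regular_grid requires kind='regular'")
    bbox = spec.bbox
    h = math.sqrt(bbox.area / spec.n_points)
    # Number of cells per axis; round so that ~h spacing fills the box.
    nx = max(1, round(bbox.width / h))
    ny = max(1, round(bbox.height / h))
    xs = bbox.xmin + h / 2.0 + h * np.arange(nx)
    ys = bbox.ymin + h / 2.0 + h * np.arange(ny)
    xs = xs[xs < bbox.xmax]
    ys = ys[ys < bbox.ymax]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    grid = LabeledGrid(
        coordinates=coords,
        labels=tuple(str(i + 1) for i in range(len(coords))),
        kind="regular",
        bbox=bbox,
        spacing=h,
    )
    return assign_labels(grid, seed=spec.seed, key=spec.key)


def make_random_grid(spec: GridSpec) -> LabeledGrid:
    """``n_points`` coordinates drawn i.i.d. uniformly from the bbox."""
    if spec.kind != "random":
        raise ValueError("make_random_grid requires kind='random'")
    rng = np.random.default_rng(spec.seed)
    bbox = spec.bbox
    x = rng.uniform(bbox.xmin, bbox.xmax, spec.n_points)
    y = rng.uniform(bbox.ymin, bbox.ymax, spec.n_points)
    grid = LabeledGrid(
        coordinates=np.column_stack([x, y]),
        labels=tuple(str(i + 1) for i in range(spec.n_points)),
        kind="random",
        bbox=bbox,
        spacing=None,
    )
    return assign_labels(grid, seed=spec.seed, key=spec.key)


def make_grid(spec: GridSpec) -> LabeledGrid:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "regular":
        return make_regular_grid(spec)
    return make_random_grid(spec)


def assign_labels(
    grid: LabeledGrid, seed: int, key: bytes | None = None
) -> LabeledGrid:
    """Relabel grid points: seeded permutation of 1..n, or keyed digests.

    Without a key, labels are a uniform random permutation of the integers
    ``1..n`` (as decimal strings), seeded for reproducibility. With a key,
    each point ``i`` gets ``HMAC-SHA256(key, i)`` (hex, truncated to 16
    chars), supporting the two-party setting where label sets double as
    hash-value sets; a truncation collision raises rather than silently
    merging two grid points.
    """
    n = len(grid)
    if key is not None:
        labels = tuple(
            hmac.new(key, str(i).encode(), hashlib.sha256).hexdigest()[:16]
            for i in range(n)
        )
        if len(set(labels)) != n:
            raise RuntimeError(
                "keyed-label collision after truncation; use a different key"
            )
    else:
        rng = np.random.default_rng(seed)
        labels = tuple(str(int(v) + 1) for v in rng.permutation(n))
    return replace(grid, labels=labels, fingerprint="", _tree=grid._tree)


def points_within(grid: LabeledGrid, center: tuple[float, float], r: float) -> set[str]:
    """Labels of grid points at Euclidean distance strictly less than ``r``.

    Uses the grid's KD-tree; membership is strict (< r), so boundary ties
    are excluded deterministically. Matches a brute-force scan exactly.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    cx, cy = float(center[0]), float(center[1])
    idx = grid.tree.query_ball_point([cx, cy], r)
    coords = grid.coordinates
    out = set()
    for i in idx:
        dx = coords[i, 0] - cx
        dy = coords[i, 1] - cy
        if dx * dx + dy * dy < r * r:  # KD-tree returns <= r; enforce strict
            out.add(grid.labels[i])
    return out
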