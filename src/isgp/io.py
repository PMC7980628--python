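"""Delimited-text file formats for the three-party workflow.

All artifacts are plain text with headers: a points file (id, x, y in
meters — data-holder side only), grid files (see :mod:`isgp.grid`),
pseudonym files (see :mod:`isgp.encoder`) and a distances file. The
pseudonym and distances files, the only ones an analyst sees, never
contain coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .encoder import PlanarPoint
from .estimator import DistanceEstimate

__all__ = [
    "read_points",
    "write_points",
    "write_distances",
    "read_distances",
]


def read_points(path: str | Path) -> list[PlanarPoint]:
    """Read a points file: delimited text with columns id, x, y (meters)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"id": str})
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"points file {path} lacks columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate point ids in {path}: {dupes[:5]}")
    return [
        PlanarPoint(str(row.id), float(row.x), float(row.y))
        for row in df.itertuples(index=False)
    ]


def write_points(points: Iterable[PlanarPoint], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": p.id, "x": p.x, "y": p.y} for p in points]
    ).to_csv(path, index=False)


_DIST_COLUMNS = ["id_p", "id_q", "s", "a_hat", "d_hat", "censored"]


def write_distances(estimates: Iterable[DistanceEstimate], path: str | Path) -> None:
    """Write per-pair results: Dice s, estimated area, distance, censoring.

    A censored row's ``d_hat`` column holds ``>=2r`` textually (the value
    ``2r`` is a bound, not an estimate).
    """
    rows = []
    for e in estimates:
        rows.append(
            {
                "id_p": e.id_p,
                "id_q": e.id_q,
                "s": e.s,
                "a_hat": e.a_hat,
                "d_hat": f">={e.d_hat!r}" if e.censored else repr(e.d_hat),
                "censored": e.censored,
            }
        )
    pd.DataFrame(rows, columns=_DIST_COLUMNS).to_csv(path, index=False)


def read_distances(path: str | Path) -> pd.DataFrame:
    """Read a distances file back; ``d_hat`` is NaN where censored."""
    df = pd.read_csv(path, dtype={"id_p": str, "id_q": str})
    df["censored"] = df["censored"].astype(bool)
    df["d_hat"] = pd.to_numeric(
        df["d_hat"].astype(str).str.removeprefix(">="), errors="coerce"
    ).where(~df["censored"])
    return df
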