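"""Synthetic geography and the factorial error study.

The generator emulates the study setting — many residential points and few
facility points in a rectangular region — without any real address data.
``run_sweep`` then reproduces the error analysis: over a full factorial of
(radius, grid count), every residential point's distances to its k nearest
facilities are approximated through the pseudonymization chain and the
signed relative errors, censoring fractions and order-preservation rates
are aggregated per cell.

Desk-scale defaults (1,000 residential points, 80 facilities, a 400 x 350
km region) preserve realistic point and grid densities rather than any
particular country's absolute counts; grid counts should be read through
the implied lattice spacing h = sqrt(area / n).
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .encoder import PlanarPoint, enlarge_bbox, encode_batch
from .estimator import estimate_distance, relative_error
from .grid import BoundingBox, GridSpec, make_grid

__all__ = [
    "SyntheticScenario",
    "SweepConfig",
    "ErrorSummary",
    "generate_scenario",
    "nearest_k",
    "run_sweep",
    "runtime_profile",
    "distance_band_study",
]

DEFAULT_REGION = BoundingBox(0.0, 0.0, 400_000.0, 350_000.0)


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of a synthetic two-population point geography.

    ``uniform`` placement scatters both populations independently and
    uniformly (the null geography, with closed-form nearest-neighbor
    behavior). ``clustered`` placement draws both populations as Gaussian
    scatter around shared cluster centers, concentrating nearest-facility
    distances in a band of a few tens of kilometers, as in health-services
    settings where residences and hospitals share population centers.
    """

    region: BoundingBox = DEFAULT_REGION
    n_residential: int = 1000
    n_facility: int = 80
    placement: Literal["uniform", "clustered"] = "uniform"
    cluster_count: int = 6
    cluster_spread: float = 30_000.0  # meters, Gaussian sd around centers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residential < 1 or self.n_facility < 1:
            raise ValueError("population counts must be >= 1")
        if self.placement not in ("uniform", "clustered"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.placement == "clustered" and self.cluster_count < 1:
            raise ValueError("cluster_count must be >= 1")


@dataclass(frozen=True)
class SweepConfig:
    """Full-factorial sweep over radii and grid counts."""

    radii: tuple[float, ...]
    grid_counts: tuple[int, ...]
    grid_kind: Literal["regular", "random"] = "regular"
    k_nearest: int = 3
    area_factor: float = 11.4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))
        object.__setattr__(self, "grid_counts", tuple(int(n) for n in self.grid_counts))
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be > 0")
        if any(n < 1 for n in self.grid_counts):
            raise ValueError("grid_counts must be >= 1")
        if self.k_nearest < 1:
            raise ValueError("k_nearest must be >= 1")


@dataclass
class ErrorSummary:
    """Aggregated sweep results.

    ``by_rank`` has one row per (radius, grid_count, rank) with the mean
    absolute relative error, the variance of signed relative errors, the
    censoring fraction and pair count; cells where every pair is censored
    carry NaN errors and ``all_censored=True``. ``by_cell`` has one row per
    (radius, grid_count) with the order-preservation rate: the fraction of
    residential points whose estimated ranking of their k nearest
    facilities equals the true ranking exactly.
    """

    by_rank: pd.DataFrame
    by_cell: pd.DataFrame

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# isgp-sweep v1\n# table=by_rank\n")
            self.by_rank.to_csv(fh, sep="\t", index=False)
            fh.write("# table=by_cell\n")
            self.by_cell.to_csv(fh, sep="\t", index=False)


def _sample_population(
    rng: np.random.Generator,
    n: int,
    region: BoundingBox,
    placement: str,
    centers: np.ndarray | None,
    spread: float,
    prefix: str,
) -> list[PlanarPoint]:
    if placement == "uniform":
        x = rng.uniform(region.xmin, region.xmax, n)
        y = rng.uniform(region.ymin, region.ymax, n)
    else:
        which = rng.integers(0, len(centers), n)
        x = centers[which, 0] + rng.normal(0.0, spread, n)
        y = centers[which, 1] + rng.normal(0.0, spread, n)
        x = np.clip(x, region.xmin, region.xmax)
        y = np.clip(y, region.ymin, region.ymax)
    return [PlanarPoint(f"{prefix}{i}", float(x[i]), float(y[i])) for i in range(n)]


def generate_scenario(
    cfg: SyntheticScenario,
) -> tuple[list[PlanarPoint], list[PlanarPoint]]:
    """Draw the residential and facility point sets of a scenario.

    Reproducible: the same config (including seed) yields identical points.
    In clustered mode both populations share the same cluster centers, and
    points are clipped to the region boundary.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = None
    if cfg.placement == "clustered":
        centers = np.column_stack(
            [
                rng.uniform(cfg.region.xmin, cfg.region.xmax, cfg.cluster_count),
                rng.uniform(cfg.region.ymin, cfg.region.ymax, cfg.cluster_count),
            ]
        )
    residential = _sample_population(
        rng, cfg.n_residential, cfg.region, cfg.placement, centers,
        cfg.cluster_spread, "res",
    )
    facility = _sample_population(
        rng, cfg.n_facility, cfg.region, cfg.placement, centers,
        cfg.cluster_spread, "fac",
    )
    return residential, facility


def nearest_k(
    facilities: list[PlanarPoint], point: PlanarPoint, k: int
) -> list[tuple[str, float]]:
    """The ``k`` facilities nearest to ``point`` by true Euclidean distance.

    Ascending distance; exact ties broken by facility id.
    """
    if k > len(facilities):
        raise ValueError(f"k={k} exceeds the number of facilities {len(facilities)}")
    pairs = [
        (f.id, float(np.hypot(f.x - point.x, f.y - point.y))) for f in facilities
    ]
    pairs.sort(key=lambda t: (t[1], t[0]))
    return pairs[:k]


def _cell_seed(master_seed: int, cell_index: int) -> int:
    return int(np.random.SeedSequence([master_seed, cell_index]).generate_state(1)[0] % (2**31))


def run_sweep(scenario: SyntheticScenario, sweep: SweepConfig) -> ErrorSummary:
    """Full-factorial error study over (radius, grid_count).

    For each cell a fresh grid (new geometry and labels, seeded from the
    master seed and cell index) is built over the enlarged region, all
    points are pseudonymized, and each residential point's distances to its
    ``k_nearest`` true-nearest facilities are approximated. Signed relative
    errors follow the (d_true - d_hat)/d_hat convention.
    """
    residential, facilities = generate_scenario(scenario)
    rank_rows = []
    cell_rows = []
    for ci, (r, n_grid) in enumerate(
        itertools.product(sweep.radii, sweep.grid_counts)
    ):
        seed = _cell_seed(sweep.seed, ci)
        bbox = enlarge_bbox(scenario.region, sweep.area_factor, min_buffer=r)
        grid = make_grid(GridSpec(sweep.grid_kind, n_grid, bbox, seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # low-cardinality noise in coarse cells
            ps_res = {
                p.id: ps
                for p, ps in zip(residential, encode_batch(residential, grid, r))
            }
            ps_fac = {
                p.id: ps
                for p, ps in zip(facilities, encode_batch(facilities, grid, r))
            }
        errors: dict[int, list[float]] = {
            rank: [] for rank in range(1, sweep.k_nearest + 1)
        }
        censored: dict[int, int] = {rank: 0 for rank in errors}
        degenerate: dict[int, int] = {rank: 0 for rank in errors}
        totals: dict[int, int] = {rank: 0 for rank in errors}
        preserved = 0
        for p in residential:
            true_order = nearest_k(facilities, p, sweep.k_nearest)
            est_list = []
            for rank, (fid, d_true) in enumerate(true_order, start=1):
                est = estimate_distance(ps_res[p.id], ps_fac[fid])
                totals[rank] += 1
                if est.censored:
                    censored[rank] += 1
                elif est.d_hat == 0.0 or d_true == 0.0:
                    # pair below the grid's resolving power (identical or
                    # coincident label sets): relative error undefined
                    degenerate[rank] += 1
                else:
                    errors[rank].append(relative_error(d_true, est))
                est_list.append((est.d_hat, fid))
            est_list.sort()
            if [fid for _, fid in est_list] == [fid for fid, _ in true_order]:
                preserved += 1
        for rank in errors:
            errs = np.array(errors[rank])
            all_censored = censored[rank] == totals[rank]
            no_errors = len(errs) == 0
            rank_rows.append(
                {
                    "radius": r,
                    "grid_count": n_grid,
                    "realized_grid_count": len(grid),
                    "rank": rank,
                    "n_pairs": totals[rank],
                    "mean_abs_rel_error": np.nan if no_errors else float(np.mean(np.abs(errs))),
                    "error_var": np.nan if no_errors else float(np.var(errs)),
                    "censor_frac": censored[rank] / totals[rank],
                    "n_degenerate": degenerate[rank],
                    "all_censored": all_censored,
                }
            )
        cell_rows.append(
            {
                "radius": r,
                "grid_count": n_grid,
                "order_preservation_rate": preserved / len(residential),
            }
        )
    return ErrorSummary(
        by_rank=pd.DataFrame(rank_rows), by_cell=pd.DataFrame(cell_rows)
    )


def distance_band_study(
    n_pairs: int,
    d_min: float,
    d_max: float,
    r: float,
    grid_spacing: float,
    seed: int,
    grid_kind: Literal["regular", "random"] = "regular",
    core_size: float = 150_000.0,
) -> pd.DataFrame:
    """Approximation error for point pairs at controlled true distances.

    Draws ``n_pairs`` pairs whose true separations are uniform on
    ``[d_min, d_max]``: the first point uniform in a ``core_size`` square,
    the second at the drawn distance in a uniform random direction. The
    grid covers the core plus a margin of ``d_max + r`` plus one lattice
    cell, so every encoding circle is fully interior. Grid density is set
    by ``grid_spacing`` (meters between lattice points, or its equivalent
    for random grids).

    Returns a frame with one row per pair: ``d_true``, ``d_hat``,
    ``censored``, and the signed ``rel_err`` (``(d_true - d_hat)/d_hat``,
    NaN where censored).
    """
    if not 0 < d_min <= d_max:
        raise ValueError("need 0 < d_min <= d_max")
    rng = np.random.default_rng(seed)
    d_true = rng.uniform(d_min, d_max, n_pairs)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_pairs)
    x1 = rng.uniform(0.0, core_size, n_pairs)
    y1 = rng.uniform(0.0, core_size, n_pairs)
    x2 = x1 + d_true * np.cos(theta)
    y2 = y1 + d_true * np.sin(theta)
    pad = d_max + r + 2.0 * grid_spacing
    bbox = BoundingBox(-pad, -pad, core_size + pad, core_size + pad)
    n_grid = round(bbox.area / grid_spacing**2)
    grid = make_grid(GridSpec(grid_kind, n_grid, bbox, seed=seed))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_pairs):
            pa = encode_batch(
                [PlanarPoint(f"a{i}", float(x1[i]), float(y1[i]))], grid, r
            )[0]
            pb = encode_batch(
                [PlanarPoint(f"b{i}", float(x2[i]), float(y2[i]))], grid, r
            )[0]
            est = estimate_distance(pa, pb)
            rows.append(
                {
                    "d_true": float(d_true[i]),
                    "d_hat": est.d_hat,
                    "censored": est.censored,
                    "rel_err": (
                        np.nan
                        if est.censored or est.d_hat == 0.0
                        else relative_error(float(d_true[i]), est)
                    ),
                }
            )
    return pd.DataFrame(rows)


def runtime_profile(scenario: SyntheticScenario, sweep: SweepConfig) -> pd.DataFrame:
    """Wall time per sweep cell, with a linear elapsed-vs-grid-count fit.

    Returns one row per (radius, grid_count) with the elapsed seconds. The
    frame's ``attrs["r_squared"]`` holds the R^2 of a least-squares linear
    fit of elapsed time against grid count (NaN with fewer than 3 cells) —
    a qualitative shape check only; absolute times are machine-dependent.
    """
    rows = []
    for r in sweep.radii:
        for n_grid in sweep.grid_counts:
            one = SweepConfig(
                radii=(r,), grid_counts=(n_grid,), grid_kind=sweep.grid_kind,
                k_nearest=sweep.k_nearest, area_factor=sweep.area_factor,
                seed=sweep.seed,
            )
            t0 = time.perf_counter()
            run_sweep(scenario, one)
            rows.append(
                {"radius": r, "grid_count": n_grid,
                 "elapsed_s": time.perf_counter() - t0}
            )
    df = pd.DataFrame(rows, columns=["radius", "grid_count", "elapsed_s"])
    if len(df) >= 3:
        coef = np.polyfit(df["grid_count"], df["elapsed_s"], 1)
        pred = np.polyval(coef, df["grid_count"])
        ss_res = float(np.sum((df["elapsed_s"] - pred) ** 2))
        ss_tot = float(np.sum((df["elapsed_s"] - df["elapsed_s"].mean()) ** 2))
        df.attrs["r_squared"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    else:
        df.attrs["r_squared"] = float("nan")
    return df
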