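"""Grid generation, labeling, radius queries and serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isgp.grid import (
    BoundingBox,
    GridSpec,
    LabeledGrid,
    assign_labels,
    make_random_grid,
    make_regular_grid,
    points_within,
)


@pytest.fixture
def unit_box():
    return BoundingBox(0.0, 0.0, 10.0, 10.0)


class TestBoundingBox:
    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(0, 0, 0, 1)
        with pytest.raises(ValueError):
            BoundingBox(0, 2, 1, 1)

    def test_of_points(self):
        box = BoundingBox.of_points([1.0, 3.0, 2.0], [5.0, 4.0, 9.0])
        assert (box.xmin, box.ymin, box.xmax, box.ymax) == (1.0, 4.0, 3.0, 9.0)


class TestRegularGrid:
    @pytest.mark.parametrize(
        "bbox, n, expected_h, expected_count",
        [
            (BoundingBox(0, 0, 10, 10), 100, 1.0, 100),
            (BoundingBox(0, 0, 10, 5), 50, 1.0, 50),
        ],
    )
    def test_exact_lattices(self, bbox, n, expected_h, expected_count):
        grid = make_regular_grid(GridSpec("regular", n, bbox, seed=0))
        assert grid.spacing == pytest.approx(expected_h)
        assert len(grid) == expected_count
        assert bbox.contains(grid.coordinates[:, 0], grid.coordinates[:, 1]).all()

    def test_spacing_from_target_count(self):
        """60,000 points over a 1.49e12 m^2 working area imply a ~4,983 m
        lattice spacing — the density regime of interest."""
        side = math.sqrt(1.49e12)
        bbox = BoundingBox(0, 0, side, side)
        grid = make_regular_grid(GridSpec("regular", 60_000, bbox, seed=0))
        assert grid.spacing == pytest.approx(4983.3, abs=1.0)
        assert len(grid) == pytest.approx(60_000, rel=0.02)

    def test_wrong_kind_rejected(self, unit_box):
        with pytest.raises(ValueError):
            make_regular_grid(GridSpec("random", 10, unit_box))

    def test_count_in_interior_circle_tracks_area(self):
        """Lattice count inside an interior circle approximates pi r^2 / h^2
        with relative deviation bounded by C h/r (C frozen at 1.5 from a
        one-off brute-force calibration)."""
        bbox = BoundingBox(0, 0, 100, 100)
        grid = make_regular_grid(GridSpec("regular", 10_000, bbox, seed=3))
        h = grid.spacing
        rng = np.random.default_rng(5)
        for r in (5.0, 10.0, 20.0):
            for _ in range(5):
                center = rng.uniform(30, 70, 2)
                count = len(points_within(grid, center, r))
                expected = math.pi * r * r / (h * h)
                assert abs(count - expected) / expected <= 1.5 * h / r


class TestRandomGrid:
    def test_single_point_inside(self, unit_box):
        grid = make_random_grid(GridSpec("random", 1, unit_box, seed=0))
        assert len(grid) == 1
        assert unit_box.contains(grid.coordinates[:, 0], grid.coordinates[:, 1]).all()

    def test_seed_determinism(self, unit_box):
        a = make_random_grid(GridSpec("random", 50, unit_box, seed=7))
        b = make_random_grid(GridSpec("random", 50, unit_box, seed=7))
        c = make_random_grid(GridSpec("random", 50, unit_box, seed=8))
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.labels == b.labels
        assert not np.array_equal(a.coordinates, c.coordinates)

    def test_quadrant_density(self):
        """Uniform sampling: each quadrant holds n/4 points within 5%."""
        bbox = BoundingBox(0, 0, 1000, 1000)
        grid = make_random_grid(GridSpec("random", 20_000, bbox, seed=11))
        x, y = grid.coordinates[:, 0], grid.coordinates[:, 1]
        for qx in (0, 1):
            for qy in (0, 1):
                n_quad = int(
                    ((x >= 500 * qx) & (x < 500 * (qx + 1))
                     & (y >= 500 * qy) & (y < 500 * (qy + 1))).sum()
                )
                assert abs(n_quad - 5000) / 5000 <= 0.05


class TestLabels:
    def test_permutation_of_1_to_n(self, unit_box):
        grid = make_regular_grid(GridSpec("regular", 100, unit_box, seed=42))
        assert sorted(int(lab) for lab in grid.labels) == list(range(1, 101))

    def test_bijection_and_determinism(self, unit_box):
        base = make_regular_grid(GridSpec("regular", 100, unit_box, seed=0))
        a = assign_labels(base, seed=5)
        b = assign_labels(base, seed=5)
        c = assign_labels(base, seed=6)
        assert a.labels == b.labels
        assert a.labels != c.labels
        assert len(set(a.labels)) == len(a)  # bijection

    def test_keyed_mode_determinism(self, unit_box):
        base = make_regular_grid(GridSpec("regular", 25, unit_box, seed=0))
        a = assign_labels(base, seed=0, key=b"shared secret")
        b = assign_labels(base, seed=99, key=b"shared secret")  # seed ignored
        c = assign_labels(base, seed=0, key=b"other secret")
        assert a.labels == b.labels
        assert a.labels != c.labels
        assert all(len(lab) == 16 for lab in a.labels)

    def test_relabeling_changes_fingerprint(self, unit_box):
        base = make_regular_grid(GridSpec("regular", 25, unit_box, seed=0))
        relabeled = assign_labels(base, seed=1)
        assert relabeled.fingerprint != base.fingerprint


class TestPointsWithin:
    def brute_force(self, grid, center, r):
        d2 = ((grid.coordinates - np.asarray(center)) ** 2).sum(axis=1)
        return {grid.labels[i] for i in np.nonzero(d2 < r * r)[0]}

    @given(
        seed=st.integers(0, 10_000),
        cx=st.floats(-2.0, 12.0),
        cy=st.floats(-2.0, 12.0),
        r=st.floats(0.01, 20.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, seed, cx, cy, r):
        """KD-tree query equals the O(n) definition on random instances."""
        grid = make_random_grid(
            GridSpec("random", 200, BoundingBox(0, 0, 10, 10), seed=seed)
        )
        assert points_within(grid, (cx, cy), r) == self.brute_force(grid, (cx, cy), r)

    def test_strict_inequality_on_boundary(self, unit_box):
        """Membership is strictly < r: a grid point at exactly r is out."""
        grid = make_regular_grid(GridSpec("regular", 100, unit_box, seed=0))
        center = tuple(grid.coordinates[0])  # on a lattice point, h = 1
        assert len(points_within(grid, center, 1.0)) == 1  # only itself
        assert len(points_within(grid, center, 0.5)) == 1

    def test_full_inclusion(self, unit_box):
        grid = make_random_grid(GridSpec("random", 200, unit_box, seed=1))
        diag = math.hypot(unit_box.width, unit_box.height)
        assert points_within(grid, (5.0, 5.0), diag) == set(grid.labels)

    def test_empty_result(self, unit_box):
        grid = make_regular_grid(GridSpec("regular", 100, unit_box, seed=0))
        assert points_within(grid, (-50.0, -50.0), 1.0) == set()


class TestSerialization:
    def test_round_trip(self, tmp_path, unit_box):
        grid = make_random_grid(
            GridSpec("random", 30, unit_box, seed=9, key=b"k")
        )
        path = tmp_path / "grid.txt"
        grid.to_file(path)
        back = LabeledGrid.from_file(path)
        assert back.labels == grid.labels
        assert np.array_equal(back.coordinates, grid.coordinates)
        assert back.kind == grid.kind
        assert back.bbox == grid.bbox
        assert back.spacing == grid.spacing
        assert back.fingerprint == grid.fingerprint

    def test_key_never_serialized(self, tmp_path, unit_box):
        grid = make_regular_grid(
            GridSpec("regular", 16, unit_box, seed=0, key=b"top secret")
        )
        path = tmp_path / "grid.txt"
        grid.to_file(path)
        assert b"top secret" not in path.read_bytes()
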