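"""Stage 4: cavity labelling, A* bridging, closed-boundary tracing."""

import math
from collections import deque

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from vtshape import (
    AnchorPoints,
    ImageRun,
    RegionOfInterest,
    TractMaskSeries,
    astar_path,
    bridge_cavities,
    find_cavities,
    outline_run,
    trace_outline,
)
from vtshape.errors import DegenerateError, NoPathError, ValidationError
from vtshape.outlining import _NEIGHBOURS

SQRT2 = math.sqrt(2.0)


def _weights(intensity, region, eps=0.01):
    vals = intensity[region]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        return eps + (intensity - lo) / (hi - lo)
    return np.full_like(intensity, eps)


def dijkstra_oracle(intensity, region, start, goal, eps=0.01):
    """Shortest-path oracle via scipy's csgraph Dijkstra, independent of the
    A* implementation."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra as sp_dijkstra

    w = _weights(intensity, region, eps)
    cells = list(zip(*np.nonzero(region)))
    index = {cell: i for i, cell in enumerate(cells)}
    graph = lil_matrix((len(cells), len(cells)))
    for (r0, c0), i in index.items():
        for dr, dc in _NEIGHBOURS:
            r1, c1 = r0 + dr, c0 + dc
            if (r1, c1) in index:
                graph[i, index[(r1, c1)]] = w[r1, c1] * (SQRT2 if dr and dc else 1.0)
    dist = sp_dijkstra(graph.tocsr(), indices=index[start])
    return dist[index[goal]]


def exhaustive_oracle(intensity, region, start, goal, eps=0.01):
    """Complete search over all simple paths (cost-pruned, but exact)."""
    w = _weights(intensity, region, eps)
    best = [np.inf]

    def visit(node, cost, seen):
        if cost >= best[0]:
            return
        if node == goal:
            best[0] = cost
            return
        r0, c0 = node
        for dr, dc in _NEIGHBOURS:
            r1, c1 = r0 + dr, c0 + dc
            if not (0 <= r1 < region.shape[0] and 0 <= c1 < region.shape[1]):
                continue
            if not region[r1, c1] or (r1, c1) in seen:
                continue
            step = w[r1, c1] * (SQRT2 if dr and dc else 1.0)
            visit((r1, c1), cost + step, seen | {(r1, c1)})

    visit(start, 0.0, {start})
    return best[0]


def flood_fill_count(mask):
    """BFS 8-connected component count, independent of scipy labelling."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    count = 0
    for r, c in zip(*np.nonzero(mask)):
        if seen[r, c]:
            continue
        count += 1
        queue = deque([(r, c)])
        seen[r, c] = True
        while queue:
            r0, c0 = queue.popleft()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r1, c1 = r0 + dr, c0 + dc
                    if (
                        0 <= r1 < mask.shape[0]
                        and 0 <= c1 < mask.shape[1]
                        and mask[r1, c1]
                        and not seen[r1, c1]
                    ):
                        seen[r1, c1] = True
                        queue.append((r1, c1))
    return count


class TestFindCavities:
    def test_two_separated_blocks(self):
        mask = np.zeros((8, 8), bool)
        mask[1:3, 1:3] = True
        mask[5:7, 5:7] = True
        assert find_cavities(mask)[1] == 2

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True
        assert find_cavities(mask)[1] == 1

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((12, 12)) > 0.6
            assert find_cavities(mask)[1] == flood_fill_count(mask)


class TestAStar:
    def test_uniform_corridor_straight_path(self):
        intensity = np.full((5, 15), 7.0)
        region = np.ones((5, 15), bool)
        path = astar_path(intensity, region, AnchorPoints(larynx=(2, 1), lips=(2, 11)))
        assert len(path.pixels) == 11
        assert all(r == 2 for r, _ in path.pixels)

    def test_handbuilt_5x5_matches_exhaustive_enumeration(self):
        intensity = np.array(
            [
                [0, 9, 9, 9, 9],
                [0, 9, 0, 0, 0],
                [0, 9, 0, 9, 0],
                [0, 9, 0, 9, 0],
                [0, 0, 0, 9, 0],
            ],
            dtype=float,
        )
        region = np.ones((5, 5), bool)
        anchors = AnchorPoints(larynx=(0, 0), lips=(0, 4))
        path = astar_path(intensity, region, anchors)
        oracle = exhaustive_oracle(intensity, region, (0, 0), (0, 4))
        assert path.total_cost == pytest.approx(oracle, abs=1e-12)

    def test_matches_dijkstra_on_random_grids(self):
        for trial in range(30):
            r = np.random.default_rng(trial)
            intensity = r.uniform(0, 100, (8, 8))
            region = r.random((8, 8)) > 0.15
            cells = list(zip(*np.nonzero(region)))
            start, goal = cells[0], cells[-1]
            oracle = dijkstra_oracle(intensity, region, start, goal)
            if np.isinf(oracle):
                with pytest.raises(NoPathError):
                    astar_path(intensity, region, AnchorPoints(start, goal))
            else:
                path = astar_path(intensity, region, AnchorPoints(start, goal))
                assert path.total_cost == pytest.approx(oracle, abs=1e-12)

    def test_anchor_outside_region_rejected(self):
        region = np.ones((4, 4), bool)
        region[0, 0] = False
        with pytest.raises(ValidationError, match="larynx"):
            astar_path(np.ones((4, 4)), region, AnchorPoints((0, 0), (3, 3)))

    def test_disconnected_anchors_raise(self):
        region = np.zeros((3, 5), bool)
        region[:, 0] = region[:, 4] = True
        with pytest.raises(NoPathError):
            astar_path(np.ones((3, 5)), region, AnchorPoints((0, 0), (0, 4)))

    def test_deterministic_path(self, rng):
        intensity = rng.uniform(0, 1, (10, 10))
        region = np.ones((10, 10), bool)
        anchors = AnchorPoints((0, 0), (9, 9))
        p1 = astar_path(intensity, region, anchors)
        p2 = astar_path(intensity, region, anchors)
        assert p1.pixels == p2.pixels


class TestBridge:
    def test_path_inside_mask_is_identity(self):
        mask = np.zeros((6, 6), bool)
        mask[2, 1:5] = True
        path = astar_path(np.zeros((6, 6)), mask, AnchorPoints((2, 1), (2, 4)))
        np.testing.assert_array_equal(bridge_cavities(mask, path), mask)

    def test_two_cavities_merge(self):
        mask = np.zeros((5, 9), bool)
        mask[2, 0:3] = True
        mask[2, 6:9] = True
        path = astar_path(np.zeros((5, 9)), np.ones((5, 9), bool), AnchorPoints((2, 0), (2, 8)))
        bridged = bridge_cavities(mask, path)
        assert find_cavities(bridged)[1] == 1

    def test_added_pixels_equal_path_minus_mask(self, rng):
        mask = rng.random((7, 7)) > 0.5
        region = np.ones((7, 7), bool)
        path = astar_path(rng.uniform(0, 1, (7, 7)), region, AnchorPoints((0, 0), (6, 6)))
        bridged = bridge_cavities(mask, path)
        added = set(zip(*np.nonzero(bridged & ~mask)))
        assert added == set(path.pixels) - set(zip(*np.nonzero(mask)))

    def test_never_removes_pixels(self, rng):
        mask = rng.random((7, 7)) > 0.5
        path = astar_path(rng.uniform(0, 1, (7, 7)), np.ones((7, 7), bool), AnchorPoints((0, 0), (6, 6)))
        assert (mask <= bridge_cavities(mask, path)).all()


class TestTraceOutline:
    def test_3x3_block_marching_squares_area(self):
        """The 0.5 iso-contour of a 3x3 block is the 3x3 square grown by half
        a pixel on each side with the four corners cut: area 9 - 4*(1/8)."""
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        outline = trace_outline(mask, frame=0)
        y, z = outline.points[:, 0], outline.points[:, 1]
        shoelace = 0.5 * abs(np.sum(y * np.roll(z, -1) - np.roll(y, -1) * z))
        assert shoelace == pytest.approx(9 - 4 * 0.125, abs=1e-12)

    def test_contour_closed_cyclically_adjacent(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        outline = trace_outline(mask, frame=0)
        gap = np.hypot(*(outline.points[0] - outline.points[-1]))
        steps = np.hypot(*np.diff(outline.points, axis=0).T)
        assert gap <= steps.max() + 1e-9

    def test_pixel_containment_oracle(self, rng):
        """True pixels fall inside the traced polygon, false pixels outside."""
        for trial in range(5):
            r = np.random.default_rng(trial)
            mask = np.zeros((10, 10), bool)
            mask[3:7, 3:7] = True
            mask[r.integers(3, 7), r.integers(3, 7)] = True
            outline = trace_outline(mask, frame=0)
            poly = Polygon([(y, z) for y, z in outline.points])
            from scipy.ndimage import binary_fill_holes

            filled = binary_fill_holes(mask)
            for row in range(10):
                for col in range(10):
                    inside = poly.buffer(1e-9).contains(Point(col, row))
                    assert inside == bool(filled[row, col])

    def test_orientation_sign_consistent(self, rng):
        areas = []
        for trial in range(5):
            r = np.random.default_rng(trial + 50)
            mask = np.zeros((12, 12), bool)
            r0, c0 = r.integers(1, 5), r.integers(1, 5)
            mask[r0 : r0 + 5, c0 : c0 + 5] = True
            areas.append(trace_outline(mask, frame=0).signed_area())
        assert all(a > 0 for a in areas)

    def test_interior_holes_filled(self):
        mask = np.zeros((9, 9), bool)
        mask[1:8, 1:8] = True
        mask[4, 4] = False
        outline = trace_outline(mask, frame=0)
        solid = mask.copy()
        solid[4, 4] = True
        ref = trace_outline(solid, frame=0)
        np.testing.assert_array_equal(outline.points, ref.points)

    def test_multiple_components_demand_bridging(self):
        mask = np.zeros((6, 6), bool)
        mask[0:2, 0:2] = True
        mask[4:6, 4:6] = True
        with pytest.raises(ValidationError, match="bridge"):
            trace_outline(mask, frame=0)

    def test_tiny_component_rejected(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        with pytest.raises(DegenerateError):
            trace_outline(mask, frame=0)


class TestOutlineRun:
    def test_no_closures_nothing_bridged(self, suite_truths):
        truth = suite_truths["clean"]
        _, records = outline_run(truth.masks, truth.run, anchors=truth.anchors)
        assert all(r["status"] == "traced" for r in records)

    def test_closure_frames_and_only_those_bridged(self, suite_truths):
        truth = suite_truths["closure"]
        _, records = outline_run(truth.masks, truth.run, anchors=truth.anchors)
        bridged = {r["frame"] for r in records if r["status"] == "bridged"}
        assert bridged == truth.closure_frames

    def test_composition_matches_manual_stages(self, suite_truths):
        truth = suite_truths["closure"]
        outlines, records = outline_run(truth.masks, truth.run, anchors=truth.anchors)
        f = min(truth.closure_frames)
        manual_path = astar_path(truth.run.intensities[f], truth.roi.mask, truth.anchors)
        manual = trace_outline(
            bridge_cavities(truth.masks.masks[f], manual_path), frame=f, lips_anchor=truth.anchors.lips
        )
        auto = next(o for o in outlines if o.frame == f)
        np.testing.assert_array_equal(auto.points, manual.points)
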