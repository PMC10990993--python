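"""Stage 4 — cavity bridging and closed-outline extraction.

An articulator closure (a stop consonant, a raised velum) can bisect the
vocal-tract mask into two or more disconnected cavities.  To model the
tract as a whole, an A* grid search walks from the larynx anchor to the
lips anchor, paying more to cross bright (tissue) pixels, so the path hugs
the dim pixels at sites of constriction.  The path is drawn into the mask
as a connector, after which a single closed boundary is traced around the
merged component with sub-pixel marching-squares contouring.

Cost model: stepping into pixel ``p`` costs ``(eps + I_hat(p)) * step_len``
where ``I_hat`` is the frame intensity min–max normalised over the search
region, ``eps`` keeps zero-intensity air traversable at a small positive
price, and ``step_len`` is 1 for axial moves and sqrt(2) for diagonal
moves.  The heuristic ``eps * Euclidean distance to goal`` never
overestimates the remaining cost, so the returned path is globally
optimal; the fixed neighbour expansion order (N, NE, E, SE, S, SW, W, NW)
plus a stable priority queue makes it bit-reproducible.
"""

from __future__ import annotations

import heapq
import math

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateError, DimensionError, NoPathError, ValidationError
from .types import AnchorPoints, ImageRun, PathResult, TractMaskSeries, TractOutline

#: default per-unit-length floor cost of the A* walk
DEFAULT_EPS = 0.01

_EIGHT = np.ones((3, 3), dtype=int)
# deterministic expansion order: N, NE, E, SE, S, SW, W, NW
_NEIGHBOURS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_SQRT2 = math.sqrt(2.0)


def find_cavities(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label the 8-connected components (cavities) of a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    labels, count = ndimage.label(mask, structure=_EIGHT)
    return labels, int(count)


def astar_path(
    frame_intensity: np.ndarray,
    search_region: np.ndarray,
    anchors: AnchorPoints,
    eps: float = DEFAULT_EPS,
) -> PathResult:
    """Minimum-cost 8-connected path from the larynx anchor to the lips anchor."""
    intensity = np.asarray(frame_intensity, dtype=np.float64)
    region = np.asarray(search_region, dtype=bool)
    if intensity.shape != region.shape:
        raise DimensionError("intensity and search region shapes differ")
    if np.any(intensity < 0):
        raise ValidationError("intensities must be non-negative")
    if eps <= 0:
        raise ValidationError("eps must be positive")
    start = (int(anchors.larynx[0]), int(anchors.larynx[1]))
    goal = (int(anchors.lips[0]), int(anchors.lips[1]))
    for name, (r, c) in (("larynx", start), ("lips", goal)):
        if not (0 <= r < region.shape[0] and 0 <= c < region.shape[1]) or not region[r, c]:
            raise ValidationError(f"{name} anchor {(r, c)} is outside the search region")

    vals = intensity[region]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        weight = eps + (intensity - lo) / (hi - lo)
    else:
        weight = np.full_like(intensity, eps)

    nrows, ncols = region.shape
    g = np.full(region.shape, np.inf)
    g[start] = 0.0
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    closed = np.zeros(region.shape, dtype=bool)

    def h(r: int, c: int) -> float:
        return eps * math.hypot(r - goal[0], c - goal[1])

    counter = 0
    heap: list[tuple[float, int, tuple[int, int]]] = [(h(*start), counter, start)]
    while heap:
        _, _, node = heapq.heappop(heap)
        if closed[node]:
            continue
        closed[node] = True
        if node == goal:
            break
        r0, c0 = node
        for dr, dc in _NEIGHBOURS:
            r1, c1 = r0 + dr, c0 + dc
            if not (0 <= r1 < nrows and 0 <= c1 < ncols):
                continue
            if not region[r1, c1] or closed[r1, c1]:
                continue
            step = _SQRT2 if dr and dc else 1.0
            cand = g[node] + weight[r1, c1] * step
            if cand < g[r1, c1]:
                g[r1, c1] = cand
                parent[(r1, c1)] = node
                counter += 1
                heapq.heappush(heap, (cand + h(r1, c1), counter, (r1, c1)))
    if not closed[goal]:
        raise NoPathError(f"anchors {start} and {goal} are disconnected within the search region")

    path = [goal]
    while path[-1] != start:
        path.append(parent[path[-1]])
    path.reverse()
    return PathResult(pixels=path, total_cost=float(g[goal]))


def bridge_cavities(mask: np.ndarray, path: PathResult) -> np.ndarray:
    """Union the connector path into the mask, merging the cavities it touches."""
    out = np.asarray(mask, dtype=bool).copy()
    rr, cc = zip(*path.pixels)
    out[list(rr), list(cc)] = True
    return out


def trace_outline(
    mask: np.ndarray,
    frame: int = 0,
    lips_anchor: tuple[int, int] | None = None,
) -> TractOutline:
    """Trace the closed outer boundary of a single-component mask.

    Interior holes are filled first so that only the outer boundary is
    traced; the contour is extracted at the 0.5 iso-level (sub-pixel
    marching squares), oriented clockwise in the (y, z) convention, and
    rotated to start at the contour point nearest the lips anchor (the
    upper margin of the lip aperture) or, absent an anchor, at the most
    superior-then-anterior point.
    """
    mask = np.asarray(mask, dtype=bool)
    _, count = find_cavities(mask)
    if count == 0:
        raise ValidationError("mask is empty; nothing to trace")
    if count > 1:
        raise ValidationError(f"mask has {count} cavities; bridge them before tracing")
    if mask.sum() < 3:
        raise DegenerateError("component has fewer than 3 pixels; too small to outline")
    filled = ndimage.binary_fill_holes(mask)
    padded = np.pad(filled.astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo the pad offset
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    # (row, col) -> (y, z) = (col, row)
    points = contour[:, ::-1].copy()
    outline = TractOutline(points, frame=frame, closed=True)
    if outline.signed_area() < 0:
        points = points[::-1].copy()
        outline = TractOutline(points, frame=frame, closed=True)
    if lips_anchor is not None:
        target = np.array([lips_anchor[1], lips_anchor[0]], dtype=float)  # (y, z)
        d = np.hypot(points[:, 0] - target[0], points[:, 1] - target[1])
        # tie-break on the more superior (smaller z) point
        start = np.lexsort((points[:, 1], np.round(d, 9)))[0]
    else:
        start = np.lexsort((points[:, 0], points[:, 1]))[0]
    points = np.roll(points, -int(start), axis=0)
    return TractOutline(points, frame=frame, closed=True)


def auto_anchors(masks: TractMaskSeries) -> AnchorPoints:
    """Fallback anchor rule when none are supplied.

    On the first non-empty frame: larynx = the most inferior (largest-row)
    mask pixel, lips = the most anterior (smallest-column) mask pixel; ties
    broken deterministically towards smaller column / smaller row.
    """
    for f in range(masks.frames):
        m = masks.masks[f]
        if m.any():
            rows, cols = np.nonzero(m)
            order = np.lexsort((cols, -rows))
            larynx = (int(rows[order[0]]), int(cols[order[0]]))
            order = np.lexsort((rows, cols))
            lips = (int(rows[order[0]]), int(cols[order[0]]))
            if larynx == lips:
                raise DegenerateError("mask too small to place distinct anchors")
            return AnchorPoints(larynx=larynx, lips=lips)
    raise ValidationError("all frames are empty; cannot place anchors")


def outline_run(
    masks: TractMaskSeries,
    run: ImageRun,
    anchors: AnchorPoints | None = None,
    eps: float = DEFAULT_EPS,
) -> tuple[list[TractOutline], list[dict]]:
    """Outline every frame, bridging multi-cavity frames with an A* connector.

    Single-cavity frames are traced directly; multi-cavity frames first get
    an A* connector computed on that frame's intensities within the search
    region (the ROI when available, otherwise the whole image).  Frames
    whose anchors fall outside the frame mask or search region are skipped
    with a logged reason rather than aborting the run.

    Returns the outlines plus one status record per frame
    (``{"frame", "status", "reason"}`` with status ``traced`` / ``bridged``
    / ``skipped``).
    """
    if run.intensities.shape != masks.shape:
        raise DimensionError("run and mask series shapes differ")
    if anchors is None:
        anchors = auto_anchors(masks)
    region = masks.roi_used.mask if masks.roi_used is not None else np.ones(masks.shape[1:], bool)
    for name, (r, c) in (("larynx", anchors.larynx), ("lips", anchors.lips)):
        if not region[r, c]:
            raise ValidationError(f"{name} anchor is outside the search region")

    outlines: list[TractOutline] = []
    records: list[dict] = []
    for f in range(masks.frames):
        mask = masks.masks[f]
        labels, count = find_cavities(mask)
        if count == 0:
            records.append({"frame": f, "status": "skipped", "reason": "empty mask"})
            continue
        if count == 1:
            if mask.sum() < 3:
                records.append({"frame": f, "status": "skipped", "reason": "component too small"})
                continue
            outlines.append(trace_outline(mask, frame=f, lips_anchor=anchors.lips))
            records.append({"frame": f, "status": "traced", "reason": ""})
            continue
        if not (mask[anchors.larynx] and mask[anchors.lips]):
            records.append(
                {"frame": f, "status": "skipped", "reason": "anchor outside frame mask"}
            )
            continue
        try:
            path = astar_path(run.intensities[f], region, anchors, eps=eps)
        except NoPathError as exc:
            records.append({"frame": f, "status": "skipped", "reason": str(exc)})
            continue
        bridged = bridge_cavities(mask, path)
        labels, count = find_cavities(bridged)
        if count > 1:
            # keep only the merged component the connector belongs to
            bridged = labels == labels[anchors.larynx]
        outlines.append(trace_outline(bridged, frame=f, lips_anchor=anchors.lips))
        records.append({"frame": f, "status": "bridged", "reason": ""})
    return outlines, records
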