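"""Validation metrics: Dice similarity, arc-length resampling, disagreement.

Dice similarity between two segmentations X and Y is

    Dice = 2 |X ∩ Y| / (|X| + |Y|)

— twice the number of shared vocal-tract pixels over the total pixel count
of both sets.  Contour-level agreement is measured after re-expressing
every analyst's closed outline as the same number of equally arc-length-
spaced sites from a shared start convention (the upper margin of the lip
aperture, proceeding clockwise): at each site the disagreement is the mean
Euclidean distance between each analyst's coordinate and the group mean
coordinate.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateError, DimensionError, ValidationError
from .types import ContourSamples, DisagreementProfile, TractOutline


def dice_score(x: np.ndarray, y: np.ndarray) -> float:
    """Dice overlap 2|X∩Y| / (|X|+|Y|) between boolean masks of equal shape."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise DimensionError(f"mask shapes differ: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 and ny == 0:
        raise DegenerateError("Dice is undefined when both masks are empty")
    return 2.0 * int((x & y).sum()) / (nx + ny)


def dice_matrix(mask_sets: Sequence[tuple[str, np.ndarray]]) -> pd.DataFrame:
    """Pairwise Dice scores between labelled mask sets (unit diagonal)."""
    if len(mask_sets) < 2:
        raise ValidationError("need at least two mask sets")
    labels = [lbl for lbl, _ in mask_sets]
    arrays = [np.asarray(m, dtype=bool) for _, m in mask_sets]
    shape = arrays[0].shape
    for lbl, a in zip(labels, arrays):
        if a.shape != shape:
            raise DimensionError(f"mask set {lbl!r} has shape {a.shape}, expected {shape}")
    n = len(arrays)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dice_score(arrays[i], arrays[j])
    return pd.DataFrame(out, index=labels, columns=labels)


def resample_contour(outline: TractOutline, n_sites: int, source: str = "") -> ContourSamples:
    """Resample a closed outline to ``n_sites`` equally spaced arc positions.

    Sites are placed at arc lengths k·L/n (k = 0 … n−1, L = perimeter) along
    the closed polyline, by linear interpolation between outline vertices;
    site 0 coincides with the outline's start point, preserving the start
    convention.
    """
    if n_sites < 2:
        raise ValidationError("n_sites must be at least 2")
    pts = np.vstack([outline.points, outline.points[:1]])
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    L = float(seglen.sum())
    if L == 0:
        raise DegenerateError("outline has zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.arange(n_sites) * (L / n_sites)
    y = np.interp(targets, cum, pts[:, 0])
    z = np.interp(targets, cum, pts[:, 1])
    return ContourSamples(np.column_stack([y, z]), source=source)


def default_n_sites(outlines: Sequence[TractOutline]) -> int:
    """The number of points in the largest outline of a set."""
    if not outlines:
        raise ValidationError("no outlines given")
    return max(o.n_points for o in outlines)


def disagreement_profile(
    samples: Sequence[ContourSamples],
    pixel_mm: tuple[float, float] = (1.0, 1.0),
    group: str = "",
) -> DisagreementProfile:
    """Per-site mean Euclidean distance of each analyst to the group mean.

    All sample sets must share the same number of sites (resample first) and
    the same start convention so that site k corresponds across analysts.
    The mm variant multiplies by the in-plane pixel size when the spacing is
    isotropic; with anisotropic spacing each axis is scaled before the
    distances are taken.
    """
    if len(samples) < 2:
        raise ValidationError("need at least two analysts")
    n_sites = samples[0].n_sites
    for s in samples:
        if s.n_sites != n_sites:
            raise ValidationError(
                "sample sets have different site counts; resample to a common n_sites first"
            )
    stack = np.stack([s.sites for s in samples])  # (analyst, site, 2)
    mean = stack.mean(axis=0)
    per_site = np.linalg.norm(stack - mean[None], axis=2).mean(axis=0)
    row_mm, col_mm = pixel_mm
    if row_mm == col_mm:
        per_site_mm = per_site * row_mm
    else:
        scaled = stack * np.array([col_mm, row_mm])  # (y, z) = (col, row)
        mean_mm = scaled.mean(axis=0)
        per_site_mm = np.linalg.norm(scaled - mean_mm[None], axis=2).mean(axis=0)
    return DisagreementProfile(
        per_site=per_site, per_site_mm=per_site_mm, group=group, n_analysts=len(samples)
    )


def mean_contour_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean distance between two closed polylines.

    The directed distance from A to B is the mean over A's vertices of the
    exact point-to-segment distance to B's closed polyline; the result is
    the average of both directions.  Used to compare traced outlines with
    phantom ground truth.
    """

    def directed(p: np.ndarray, q: np.ndarray) -> float:
        q2 = np.vstack([q, q[:1]])
        starts, ends = q2[:-1], q2[1:]
        d = ends - starts  # (m, 2)
        len2 = (d**2).sum(axis=1)
        len2[len2 == 0] = 1.0
        # project every point of p onto every segment of q
        diff = p[:, None, :] - starts[None, :, :]  # (n, m, 2)
        t = np.clip((diff * d[None]).sum(axis=2) / len2[None], 0.0, 1.0)
        proj = starts[None] + t[..., None] * d[None]
        dist = np.linalg.norm(p[:, None, :] - proj, axis=2).min(axis=1)
        return float(dist.mean())

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return 0.5 * (directed(a, b) + directed(b, a))
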