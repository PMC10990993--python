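"""Stages 2–3 — frame selection and quality assurance.

Stage 2 keeps only the frames a logfile marks as interesting (e.g. frames
with audible speech) and discards the rest.  Stage 3 summarises the
retained classification as a per-pixel proportion map — the fraction of
frames in which each pixel was called vocal tract — which makes
systematically misclassified pockets easy to spot; the analyst then
excludes such pixels once per run and the exclusion is extrapolated to all
frames.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DimensionError, ValidationError
from .types import ExclusionMask, FrameSelectionLog, QAMap, RegionOfInterest, TractMaskSeries
from .masking import _rasterise


def select_frames(
    masks: TractMaskSeries, log: FrameSelectionLog
) -> tuple[TractMaskSeries, dict[int, int]]:
    """Retain the union of logged [onset, offset] frame intervals.

    Intervals are inclusive on both ends; overlaps are unioned so each
    frame appears at most once, in original temporal order.  Returns the
    trimmed series and the old→new frame index mapping.
    """
    n = masks.frames
    for i, seg in enumerate(log.segments):
        if seg.offset >= n or seg.onset < 0:
            raise ValidationError(
                f"segment {i} ({seg.label!r}) [{seg.onset}, {seg.offset}] outside run of {n} frames"
            )
    keep: set[int] = set()
    for seg in log.segments:
        keep.update(range(seg.onset, seg.offset + 1))
    if not keep:
        warnings.warn("empty frame-selection log: no frames retained", stacklevel=2)
    retained = sorted(keep)
    mapping = {old: new for new, old in enumerate(retained)}
    sub = masks.masks[retained] if retained else masks.masks[:0]
    return (
        TractMaskSeries(sub, roi_used=masks.roi_used, threshold_used=masks.threshold_used),
        mapping,
    )


def compute_qa_map(masks: TractMaskSeries) -> QAMap:
    """Per-pixel proportion of frames classified as vocal tract."""
    if masks.frames == 0:
        raise ValidationError("cannot build a QA map from zero frames")
    return QAMap(masks.masks.mean(axis=0), n_frames=masks.frames)


def exclusion_from_polygons(shape: tuple[int, int], polygons) -> ExclusionMask:
    """Build an exclusion mask from analyst (row, col) polygon lists."""
    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        mask |= _rasterise(poly, shape)
    return ExclusionMask(
        mask, provenance=[{"op": "exclude", "polygons": [np.asarray(p, float).tolist() for p in polygons]}]
    )


def apply_exclusions(masks: TractMaskSeries, excl: ExclusionMask) -> TractMaskSeries:
    """Force excluded pixels to False in every frame; idempotent."""
    if excl.mask.shape != masks.shape[1:]:
        raise DimensionError("exclusion mask shape does not match the series")
    out = masks.masks & ~excl.mask[None, :, :]
    return TractMaskSeries(out, roi_used=masks.roi_used, threshold_used=masks.threshold_used)


def render_qa_png(qa: QAMap, reference_frame: np.ndarray, path) -> None:
    """Render the QA map as a translucent→opaque pink overlay on a reference frame.

    The PNG is for human review only; the numeric map is the canonical
    artifact.
    """
    import imageio.v3 as iio

    ref = np.asarray(reference_frame, dtype=np.float64)
    if ref.shape != qa.proportion.shape:
        raise DimensionError("reference frame shape does not match the QA map")
    span = np.ptp(ref)
    grey = (ref - ref.min()) / span if span > 0 else np.zeros_like(ref)
    pink = np.array([255.0, 105.0, 180.0])
    alpha = qa.proportion[..., None]
    rgb = (1.0 - alpha) * (grey[..., None] * 255.0) + alpha * pink
    iio.imwrite(path, rgb.round().astype(np.uint8))
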