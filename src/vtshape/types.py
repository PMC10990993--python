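"""Domain containers for the vocal-tract shape pipeline.

Axis conventions
----------------
Image stacks are stored as ``(frame, row, col)``.  In the midsagittal plane
the column index increases from anterior (lips) to posterior and is referred
to as the *y* axis; the row index increases from superior to inferior and is
the *z* axis.  Outline coordinates are therefore stored as ``(y, z)`` =
``(col, row)`` pairs, while pixel coordinates used for anchors, polygons and
paths are ``(row, col)``.

Frame indexing is 0-based everywhere inside the library.  Logfiles on disk
use 1-based inclusive frame numbers (see :func:`vtshape.io.read_logfile`,
which performs the conversion exactly once).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import DimensionError, ValidationError


class Segment(NamedTuple):
    """One retained interval of frames, 0-based and inclusive on both ends."""

    onset: int
    offset: int
    label: str = ""


@dataclass
class ImageRun:
    """A dynamic 2-D image sequence: one midsagittal slice over time.

    Parameters
    ----------
    intensities : ndarray, shape (frames, rows, cols)
        Non-negative T1-weighted signal values.
    fps : float
        Temporal resolution in frames per second.  ``nan`` marks unknown;
        the five processing stages never require it.
    pixel_mm : (float, float)
        In-plane pixel spacing as (row spacing, col spacing) in millimetres.
    run_id : str
        Free-text identifier carried through to outputs.
    """

    intensities: np.ndarray
    fps: float = math.nan
    pixel_mm: tuple[float, float] = (1.0, 1.0)
    run_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise DimensionError(
                f"ImageRun requires a (frame, row, col) stack; got ndim={self.intensities.ndim}"
            )
        if self.frames < 1:
            raise ValidationError("ImageRun requires at least one frame")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("ImageRun intensities must all be finite")
        if np.any(self.intensities < 0):
            raise ValidationError("ImageRun intensities must be non-negative")
        self.pixel_mm = (float(self.pixel_mm[0]), float(self.pixel_mm[1]))
        if not (self.pixel_mm[0] > 0 and self.pixel_mm[1] > 0):
            raise ValidationError("pixel_mm components must be positive")
        self.fps = float(self.fps)

    @property
    def frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def rows(self) -> int:
        return self.intensities.shape[1]

    @property
    def cols(self) -> int:
        return self.intensities.shape[2]

    def with_intensities(self, intensities: np.ndarray) -> "ImageRun":
        """Copy of this run with new pixel data but identical metadata."""
        return ImageRun(intensities, fps=self.fps, pixel_mm=self.pixel_mm, run_id=self.run_id)


@dataclass
class FrameSelectionLog:
    """Segments of frames to retain, 0-based inclusive, ordered by onset."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = [Segment(int(s[0]), int(s[1]), str(s[2]) if len(s) > 2 else "") for s in self.segments]
        for i, s in enumerate(segs):
            if s.onset > s.offset:
                raise ValidationError(f"segment {i}: onset {s.onset} > offset {s.offset}")
            if s.onset < 0:
                raise ValidationError(f"segment {i}: negative onset {s.onset}")
        self.segments = sorted(segs, key=lambda s: (s.onset, s.offset))


@dataclass
class RegionOfInterest:
    """Boolean pixel grid confining classification to analyst-approved space."""

    mask: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DimensionError("ROI mask must be 2-D (row, col)")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class VarianceMap:
    """Per-pixel temporal variance of an image run."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError("variance map must be 2-D")
        if np.any(self.values < 0):
            raise ValidationError("variance cannot be negative")


@dataclass
class ThresholdModel:
    """Air/tissue intensity threshold fitted from a bimodal pooled histogram.

    ``threshold`` sits at the density minimum between the two KDE modes when
    ``bimodality_ok``; otherwise it is an Otsu fallback and a warning was
    issued at fit time.
    """

    threshold: float
    density_grid: tuple[np.ndarray, np.ndarray]
    mode_locations: Optional[tuple[float, float]]
    bimodality_ok: bool


@dataclass
class TractMaskSeries:
    """Per-frame boolean masks marking vocal-tract (air) pixels."""

    masks: np.ndarray
    roi_used: Optional[RegionOfInterest] = None
    threshold_used: float = math.nan

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise DimensionError("mask series must be (frame, row, col)")
        if self.roi_used is not None:
            if self.roi_used.mask.shape != self.masks.shape[1:]:
                raise DimensionError("ROI shape does not match mask series")
            outside = self.masks & ~self.roi_used.mask[None, :, :]
            if outside.any():
                raise ValidationError("mask series contains pixels outside its ROI")

    @property
    def frames(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks.shape


@dataclass
class QAMap:
    """Per-pixel proportion of frames classified as vocal tract."""

    proportion: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.proportion = np.asarray(self.proportion, dtype=np.float64)
        if self.proportion.ndim != 2:
            raise DimensionError("QA map must be 2-D")
        if np.any(self.proportion < 0) or np.any(self.proportion > 1):
            raise ValidationError("QA proportions must lie in [0, 1]")


@dataclass
class ExclusionMask:
    """Pixels flagged for removal from every frame of a run (True = exclude)."""

    mask: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DimensionError("exclusion mask must be 2-D")


class AnchorPoints(NamedTuple):
    """Fixed path endpoints in (row, col) pixel coordinates."""

    larynx: tuple[int, int]
    lips: tuple[int, int]


@dataclass
class PathResult:
    """An 8-connected pixel path from the larynx anchor to the lips anchor."""

    pixels: list[tuple[int, int]]
    total_cost: float

    def __post_init__(self) -> None:
        if len(self.pixels) < 1:
            raise ValidationError("path must contain at least one pixel")
        for (r0, c0), (r1, c1) in zip(self.pixels, self.pixels[1:]):
            if max(abs(r0 - r1), abs(c0 - c1)) != 1:
                raise ValidationError("consecutive path pixels must be 8-neighbours")
        if len(set(self.pixels)) != len(self.pixels):
            raise ValidationError("path revisits a pixel")
        if self.total_cost < 0:
            raise ValidationError("path cost cannot be negative")


@dataclass
class TractOutline:
    """Ordered closed boundary of the vocal tract for one frame.

    Points are ``(y, z)`` coordinates (col, row) proceeding clockwise from
    the site nearest the upper margin of the lip aperture.
    """

    points: np.ndarray
    frame: int
    closed: bool = True
    start_convention: str = "upper-lip-clockwise"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise DimensionError("outline points must be an (n, 2) array of (y, z)")
        if len(self.points) < 3:
            raise ValidationError("an outline needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("outline coordinates must be finite")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        """Shoelace area in the (y, z) plane; sign encodes orientation."""
        y = self.points[:, 0]
        z = self.points[:, 1]
        return 0.5 * float(np.sum(y * np.roll(z, -1) - np.roll(y, -1) * z))

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


@dataclass
class ContourSamples:
    """A contour re-expressed as equally arc-length-spaced measurement sites."""

    sites: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.float64)
        if self.sites.ndim != 2 or self.sites.shape[1] != 2:
            raise DimensionError("sites must be an (n, 2) array of (y, z)")
        if len(self.sites) < 2:
            raise ValidationError("need at least 2 sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class DisagreementProfile:
    """Per-site mean distance of each analyst's contour to the group mean."""

    per_site: np.ndarray
    per_site_mm: np.ndarray
    group: str
    n_analysts: int

    def __post_init__(self) -> None:
        self.per_site = np.asarray(self.per_site, dtype=np.float64)
        self.per_site_mm = np.asarray(self.per_site_mm, dtype=np.float64)
        if np.any(self.per_site < 0) or np.any(self.per_site_mm < 0):
            raise ValidationError("disagreement values cannot be negative")


@dataclass
class BiasField:
    """A smooth multiplicative gain field, normalised to mean 1."""

    field: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float64)
        if self.field.ndim != 2:
            raise DimensionError("bias field must be 2-D")
        if np.any(self.field <= 0):
            raise ValidationError("bias field values must be strictly positive")
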