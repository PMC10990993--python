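"""Stage 1 — spatially informed tissue classification.

The vocal tract appears as dark (air) pixels between bright soft-tissue
structures.  Because the tract moves while everything else holds still, the
per-pixel temporal variance of a run traces its course; thresholding that
variance map seeds a region of interest (ROI), which the analyst then
refines with polygon edits.  Pooling the ROI's intensities across all
frames gives a bimodal distribution — an air mode and a tissue mode — and
the kernel-density minimum between the two modes is the classification
threshold.  Pixels strictly below the threshold are air (vocal tract);
pixels at or above it are tissue.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal, stats
from skimage import draw
from skimage.filters import threshold_otsu

from .errors import DegenerateError, DimensionError, ValidationError
from .types import ImageRun, RegionOfInterest, ThresholdModel, TractMaskSeries, VarianceMap

#: number of evaluation points for the pooled-intensity KDE
KDE_GRID_POINTS = 512
#: a KDE maximum counts as a mode only if its density reaches this fraction
#: of the global density maximum
MODE_PROMINENCE_FLOOR = 0.05
#: default variance quantile for ROI seeding
DEFAULT_SEED_QUANTILE = 0.75


def compute_variance_map(run: ImageRun) -> VarianceMap:
    """Per-pixel population variance (divisor = number of frames) over time."""
    if run.frames < 2:
        raise ValidationError("variance needs at least 2 frames")
    return VarianceMap(np.var(run.intensities, axis=0, ddof=0))


def seed_roi(vmap: VarianceMap, quantile: float = DEFAULT_SEED_QUANTILE) -> RegionOfInterest:
    """Seed an ROI from pixels with variance strictly above a quantile cutoff."""
    if not 0 < quantile < 1:
        raise ValidationError("quantile must lie strictly between 0 and 1")
    values = vmap.values
    if not values.any():
        raise DegenerateError(
            "variance map is all zero; the run is static — define the ROI manually with edit_roi"
        )
    cutoff = float(np.quantile(values, quantile))
    mask = values > cutoff
    if not mask.any():
        raise DegenerateError("no pixel exceeds the variance cutoff; lower the quantile")
    return RegionOfInterest(
        mask, provenance=[{"op": "seed", "quantile": quantile, "cutoff": cutoff}]
    )


def _rasterise(polygon, shape) -> np.ndarray:
    poly = np.asarray(polygon, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValidationError("a polygon needs at least 3 (row, col) vertices")
    if (
        poly[:, 0].min() < 0
        or poly[:, 1].min() < 0
        or poly[:, 0].max() > shape[0] - 1
        or poly[:, 1].max() > shape[1] - 1
    ):
        raise ValidationError("polygon vertices must lie within the image bounds")
    rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def edit_roi(roi: RegionOfInterest, additions=(), removals=()) -> RegionOfInterest:
    """Apply analyst polygon edits: additions first, then removals.

    Removals win wherever an addition and a removal overlap.  Polygons are
    lists of (row, col) vertices; the edit is recorded in the ROI's
    provenance so the session is auditable.
    """
    mask = roi.mask.copy()
    for poly in additions:
        mask |= _rasterise(poly, mask.shape)
    for poly in removals:
        mask &= ~_rasterise(poly, mask.shape)
    record = {
        "op": "edit",
        "additions": [np.asarray(p, dtype=float).tolist() for p in additions],
        "removals": [np.asarray(p, dtype=float).tolist() for p in removals],
    }
    return RegionOfInterest(mask, provenance=list(roi.provenance) + [record])


def fit_threshold(run: ImageRun, roi: RegionOfInterest) -> ThresholdModel:
    """Fit the air/tissue threshold from the pooled ROI intensity histogram.

    All frames contribute: the histogram of ROI-pixel intensities pooled
    across the run is smoothed with a Gaussian KDE (Silverman bandwidth,
    512-point grid over the observed range).  The two highest-density local
    maxima whose density reaches 5% of the global maximum are taken as the
    air and tissue modes, and the threshold is placed at the density minimum
    between them (midpoint of the plateau when the minimum is flat).  If
    fewer than two qualifying modes exist the distribution is declared
    non-bimodal: ``bimodality_ok`` is False, a warning is issued, and an
    Otsu threshold on the pooled sample is used as fallback.
    """
    if roi.mask.shape != run.intensities.shape[1:]:
        raise DimensionError("ROI shape does not match the run")
    if not roi.mask.any():
        raise ValidationError("ROI is empty; cannot fit a threshold")
    values = run.intensities[:, roi.mask].ravel()
    if np.ptp(values) == 0:
        raise DegenerateError("ROI intensities are constant; no threshold exists")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    # extend the grid a few bandwidths past the observed range so that a
    # mode sitting exactly at the data minimum or maximum (noise-free data)
    # is an interior peak rather than an undetectable boundary point
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, KDE_GRID_POINTS)
    density = kde(grid)

    peaks, _ = signal.find_peaks(density)
    peaks = peaks[density[peaks] >= MODE_PROMINENCE_FLOOR * density.max()]
    if len(peaks) < 2:
        warnings.warn(
            "pooled intensity distribution is not bimodal; falling back to Otsu threshold",
            stacklevel=2,
        )
        return ThresholdModel(
            threshold=float(threshold_otsu(values)),
            density_grid=(grid, density),
            mode_locations=None,
            bimodality_ok=False,
        )
    # the two strongest modes, in increasing intensity order
    top2 = peaks[np.argsort(density[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    between = density[lo + 1 : hi]
    min_val = between.min()
    flat = np.flatnonzero(between == min_val) + lo + 1
    threshold = 0.5 * (grid[flat[0]] + grid[flat[-1]])
    return ThresholdModel(
        threshold=float(threshold),
        density_grid=(grid, density),
        mode_locations=(float(grid[lo]), float(grid[hi])),
        bimodality_ok=True,
    )


def classify_run(run: ImageRun, roi: RegionOfInterest, model: ThresholdModel) -> TractMaskSeries:
    """Classify every frame: vocal tract = ROI ∧ (intensity < threshold).

    Pixels exactly at the threshold are tissue (deterministic boundary
    rule).  The same threshold is applied iteratively across all frames of
    the run.
    """
    if roi.mask.shape != run.intensities.shape[1:]:
        raise DimensionError("ROI shape does not match the run")
    if not np.isfinite(model.threshold):
        raise ValidationError("threshold must be finite")
    masks = (run.intensities < model.threshold) & roi.mask[None, :, :]
    return TractMaskSeries(masks, roi_used=roi, threshold_used=model.threshold)
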