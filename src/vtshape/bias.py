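"""Intensity-inhomogeneity (bias field) estimation and correction.

MRI shimming leaves behind a smooth multiplicative gain field: the same
tissue appears brighter in one part of the image than another, which
degrades threshold-based tissue classification.  The field is estimated
homomorphically — large-kernel Gaussian smoothing of the log-intensity of a
reference image (the temporal mean by default) — or, alternatively, by
fitting a low-order polynomial surface to the log intensities.  Air pixels
(near zero signal) are excluded from the fit via a low-percentile floor,
because the bias is a tissue-signal phenomenon and the log of near-zero
values is numerically unstable.  Correction divides every frame by the
mean-one field and is always an explicit, opt-in step: whether it helps
should be decided per dataset.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DimensionError, EstimationError, ValidationError
from .types import BiasField, ImageRun

#: intensity percentile below which pixels are treated as air and excluded
AIR_FLOOR_PERCENTILE = 10.0


def estimate_bias_field(
    run: ImageRun,
    smoothing_scale: float = 30.0,
    reference: str = "temporal_mean",
    reference_frame: int = 0,
    model: str = "gaussian",
    air_floor_percentile: float = AIR_FLOOR_PERCENTILE,
) -> BiasField:
    """Estimate a smooth multiplicative gain field from one reference image.

    Parameters
    ----------
    smoothing_scale : float
        Gaussian sigma in pixels (> 1); the estimated field varies only at
        scales of this order or larger.
    reference : {"temporal_mean", "single_frame"}
        Image from which to estimate; the temporal mean averages out
        articulation and noise.
    model : {"gaussian", "polynomial"}
        Homomorphic Gaussian smoothing, or a second-order log-domain
        polynomial surface.
    """
    if smoothing_scale <= 1:
        raise ValidationError("smoothing_scale must exceed 1 pixel")
    if reference == "temporal_mean":
        ref = run.intensities.mean(axis=0)
    elif reference == "single_frame":
        ref = run.intensities[reference_frame]
    else:
        raise ValidationError(f"unknown reference {reference!r}")
    if not np.any(ref > 0):
        raise EstimationError("reference image is all zero; cannot estimate a bias field")

    floor = np.percentile(ref, air_floor_percentile)
    valid = (ref >= floor) & (ref > 0)
    if valid.sum() < 16:
        raise EstimationError("too few tissue pixels above the air floor to estimate a field")
    log_ref = np.zeros_like(ref)
    log_ref[valid] = np.log(ref[valid])

    # second-order log-domain polynomial trend; finite-kernel smoothing alone
    # attenuates a field that spans the whole image, so the Gaussian model
    # smooths only the residual around this trend and adds the trend back
    rr, cc = np.mgrid[0 : ref.shape[0], 0 : ref.shape[1]]
    r = (rr - rr.mean()) / max(ref.shape[0], 1)
    c = (cc - cc.mean()) / max(ref.shape[1], 1)
    design = np.stack([np.ones_like(r), r, c, r * c, r**2, c**2], axis=-1)
    coef, *_ = np.linalg.lstsq(design[valid], log_ref[valid], rcond=None)
    trend = design @ coef

    if model == "gaussian":
        w = valid.astype(np.float64)
        resid = (log_ref - trend) * w
        num = ndimage.gaussian_filter(resid, smoothing_scale, mode="constant", cval=0.0)
        den = ndimage.gaussian_filter(w, smoothing_scale, mode="constant", cval=0.0)
        smooth = trend + np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
        tag = f"gaussian:sigma={smoothing_scale:g}"
    elif model == "polynomial":
        smooth = trend
        tag = "polynomial:order=2"
    else:
        raise ValidationError(f"unknown bias model {model!r}")

    # remove the overall gain so only the spatial *shape* of the field remains
    field = np.exp(smooth - smooth[valid].mean())
    field /= field.mean()
    return BiasField(field=field, model=tag)


def correct_run(run: ImageRun, field: BiasField) -> ImageRun:
    """Divide every frame pixel-wise by the bias field; metadata unchanged."""
    if field.field.shape != run.intensities.shape[1:]:
        raise DimensionError("bias field shape does not match the run")
    return run.with_intensities(run.intensities / field.field[None, :, :])
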