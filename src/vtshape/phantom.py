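"""Synthetic midsagittal phantoms with exact ground truth.

The phantom emulates the features of a real midsagittal rtMRI run that the
pipeline exercises: bright soft tissue surrounding a dark, curved,
tube-like air space running from the lips to the larynx; frames in which
an articulator closure interrupts the tube and splits it into two
cavities; additive Gaussian noise; and a smooth multiplicative gain
(bias) field.  The tube is an offset band around a spline-interpolated
centreline; its width oscillates slowly over time to mimic articulation,
which also gives the temporal-variance map something to see.  No real
anatomy (velum, epiglottis, teeth) is modelled — the phantom tests
signal-processing behaviour, not anatomical realism.

All randomness flows from a single seed; each frame's noise is drawn from
an independently derived stream so frame k is identical no matter how many
frames follow it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .errors import ValidationError
from .outlining import trace_outline
from .types import AnchorPoints, ImageRun, RegionOfInterest, TractMaskSeries, TractOutline

#: dense samples along the centreline used for rasterisation
_CENTRELINE_SAMPLES = 1024

# a gentle curve from the anterior-superior "lips" down to the
# posterior-inferior "larynx", scaled to the image size (row, col fractions)
_DEFAULT_CENTRELINE = (
    (0.22, 0.09),
    (0.19, 0.34),
    (0.31, 0.59),
    (0.53, 0.72),
    (0.81, 0.75),
)


@dataclass(frozen=True)
class ClosureEvent:
    """An articulator closure: the tube is interrupted for a span of frames.

    ``position`` is the normalised arc position (0 = lips, 1 = larynx) of
    the closure centre; ``length_px`` its extent along the centreline;
    ``residual`` the closure's image intensity as a fraction of the
    air→tissue contrast (a constriction is dimmer than bulk tissue, which
    is what lets the A* connector cross it more cheaply than bulk
    tissue).  The default 0.8 reflects a closed articulator: bulk tissue,
    dimmed only by partial-volume averaging at the contact surface.
    """

    frame_start: int
    frame_end: int  # inclusive
    position: float
    residual: float = 0.8
    length_px: float = 3.0


@dataclass
class PhantomSpec:
    rows: int = 64
    cols: int = 64
    frames: int = 50
    centreline: Sequence[tuple[float, float]] = _DEFAULT_CENTRELINE
    centreline_fractional: bool = True
    tube_width: float = 5.0
    width_modulation: float = 0.1
    closure_events: tuple[ClosureEvent, ...] = ()
    tissue_level: float = 100.0
    air_level: float = 10.0
    noise_sigma: float = 0.0
    bias_model: Optional[str] = None  # e.g. "linear_ramp"
    bias_amplitude: float = 0.0
    seed: int = 0
    run_id: str = "phantom"

    def __post_init__(self) -> None:
        if not self.tissue_level > self.air_level >= 0:
            raise ValidationError("need tissue_level > air_level >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        for ev in self.closure_events:
            if not 0.0 < ev.position < 1.0:
                raise ValidationError("closure position must lie on the open centreline (0, 1)")
            if not 0 <= ev.frame_start <= ev.frame_end:
                raise ValidationError("invalid closure frame range")

    @property
    def contrast(self) -> float:
        return self.tissue_level - self.air_level


@dataclass
class PhantomTruth:
    """A generated run paired with its exact ground truth."""

    run: ImageRun
    masks: TractMaskSeries
    outlines: list[TractOutline]
    anchors: AnchorPoints
    roi: RegionOfInterest
    spec: PhantomSpec

    @property
    def closure_frames(self) -> set[int]:
        out: set[int] = set()
        for ev in self.spec.closure_events:
            out.update(range(ev.frame_start, min(ev.frame_end, self.run.frames - 1) + 1))
        return out


def _dense_centreline(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Spline-resampled centreline: (points (S,2) row/col, arc position s, length)."""
    ctrl = np.asarray(spec.centreline, dtype=np.float64)
    if spec.centreline_fractional:
        ctrl = ctrl * np.array([spec.rows - 1, spec.cols - 1])
    if len(ctrl) < 2:
        raise ValidationError("centreline needs at least 2 control points")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))])
    if chord[-1] == 0:
        raise ValidationError("centreline control points are coincident")
    t = chord / chord[-1]
    spline = CubicSpline(t, ctrl, axis=0)
    dense = spline(np.linspace(0.0, 1.0, _CENTRELINE_SAMPLES))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(arc[-1])
    return dense, arc / length, length


def _bias_field(spec: PhantomSpec) -> np.ndarray:
    if spec.bias_model is None or spec.bias_amplitude == 0:
        return np.ones((spec.rows, spec.cols))
    if spec.bias_model == "linear_ramp":
        ramp = np.linspace(-1.0, 1.0, spec.cols)
        return np.tile(1.0 + spec.bias_amplitude * ramp, (spec.rows, 1))
    if spec.bias_model == "gaussian_bump":
        rr, cc = np.mgrid[0 : spec.rows, 0 : spec.cols]
        r0, c0 = (spec.rows - 1) / 2, (spec.cols - 1) / 2
        sigma = 0.5 * max(spec.rows, spec.cols)
        bump = np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)))
        return 1.0 + spec.bias_amplitude * (bump - bump.mean())
    raise ValidationError(f"unknown bias model {spec.bias_model!r}")


def _frame_rng(seed: int, frame: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(frame,)))


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a run, truth masks, truth outlines and anchors from a spec."""
    dense, s_vals, length = _dense_centreline(spec)
    max_halfwidth = spec.tube_width * (1 + abs(spec.width_modulation)) / 2
    if (
        dense[:, 0].min() < max_halfwidth
        or dense[:, 1].min() < max_halfwidth
        or dense[:, 0].max() > spec.rows - 1 - max_halfwidth
        or dense[:, 1].max() > spec.cols - 1 - max_halfwidth
    ):
        raise ValidationError("tube geometry extends outside the image bounds")

    rr, cc = np.mgrid[0 : spec.rows, 0 : spec.cols]
    pixels = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    dist, idx = cKDTree(dense).query(pixels)
    dist = dist.reshape(spec.rows, spec.cols)
    s_near = s_vals[idx].reshape(spec.rows, spec.cols)

    bias = _bias_field(spec)
    stack = np.empty((spec.frames, spec.rows, spec.cols))
    truth = np.empty((spec.frames, spec.rows, spec.cols), dtype=bool)
    full_tube_union = np.zeros((spec.rows, spec.cols), dtype=bool)
    full_tubes: list[np.ndarray] = []

    for f in range(spec.frames):
        width_f = spec.tube_width * (
            1.0 + spec.width_modulation * math.sin(2.0 * math.pi * f / spec.frames)
        )
        tube = dist <= width_f / 2.0
        full_tubes.append(tube)
        full_tube_union |= tube

        closure_zone = np.zeros_like(tube)
        residual_img = np.zeros((spec.rows, spec.cols))
        for ev in spec.closure_events:
            if ev.frame_start <= f <= ev.frame_end:
                half_ds = (ev.length_px / 2.0) / length
                zone = tube & (np.abs(s_near - ev.position) <= half_ds)
                closure_zone |= zone
                residual_img[zone] = spec.air_level + ev.residual * spec.contrast
        truth[f] = tube & ~closure_zone

        img = np.full((spec.rows, spec.cols), spec.tissue_level)
        img[tube] = spec.air_level
        img[closure_zone] = residual_img[closure_zone]
        if spec.noise_sigma > 0:
            img = img + _frame_rng(spec.seed, f).normal(0.0, spec.noise_sigma, img.shape)
        stack[f] = np.maximum(img * bias, 0.0)

    run = ImageRun(stack, fps=math.nan, pixel_mm=(1.0, 1.0), run_id=spec.run_id)
    roi = RegionOfInterest(
        binary_dilation(full_tube_union, iterations=2),
        provenance=[{"op": "phantom-truth-roi", "dilation": 2}],
    )
    lips = tuple(int(round(v)) for v in dense[0])
    larynx = tuple(int(round(v)) for v in dense[-1])
    anchors = AnchorPoints(larynx=larynx, lips=lips)

    outlines = []
    from .outlining import find_cavities  # local import to avoid cycle at module load

    for f in range(spec.frames):
        _, count = find_cavities(truth[f])
        # during a closure the ideal whole-tract outline encircles the full
        # (uninterrupted) tube, which is what a bridged trace approximates
        target = truth[f] if count == 1 else full_tubes[f]
        outlines.append(trace_outline(target, frame=f, lips_anchor=anchors.lips))

    masks = TractMaskSeries(truth, roi_used=roi, threshold_used=math.nan)
    return PhantomTruth(run=run, masks=masks, outlines=outlines, anchors=anchors, roi=roi, spec=spec)


def default_validation_suite(seed: int = 0) -> list[PhantomSpec]:
    """The fixed five-phantom battery used for validation.

    All members are 64×64×50.  Noise, where present, has sigma equal to
    10% of the air–tissue contrast.  The bias member combines a 30% linear
    gain ramp with reduced air–tissue contrast (air 60, tissue 100), the
    regime in which a gain ramp genuinely entangles the two intensity
    modes; at the default 10:1 contrast a 30% ramp leaves the modes
    separable and classification would be unaffected.
    """

    def sub_seed(i: int) -> int:
        return (seed * 1000003 + i) % (2**31)

    closure = (ClosureEvent(frame_start=5, frame_end=8, position=0.5, residual=0.8, length_px=3.0),)
    return [
        PhantomSpec(run_id="clean", seed=sub_seed(0)),
        PhantomSpec(run_id="noisy", noise_sigma=9.0, seed=sub_seed(1)),
        PhantomSpec(run_id="closure", closure_events=closure, seed=sub_seed(2)),
        PhantomSpec(
            run_id="bias",
            air_level=60.0,
            bias_model="linear_ramp",
            bias_amplitude=0.3,
            seed=sub_seed(3),
        ),
        PhantomSpec(
            run_id="combined",
            noise_sigma=9.0,
            closure_events=closure,
            bias_model="linear_ramp",
            bias_amplitude=0.3,
            seed=sub_seed(4),
        ),
    ]
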