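# Methods

## Coordinate and index conventions

Image stacks are `(frame, row, col)` with the frame axis always first. In
the midsagittal plane the column index is the anatomical *y* axis
(anterior → posterior) and the row index is *z* (superior → inferior);
outline coordinates are stored `(y, z)`. Logfiles on disk carry 1-based
inclusive frame numbers (the convention of the Praat/MATLAB tools that
produce them); `read_logfile` converts to 0-based inclusive indices exactly
once, and nothing else in the library ever re-converts. TextGrid interval
times map to frames as `onset = floor(t_start·fps)`,
`offset = ceil(t_end·fps)`, clamped to the run — outward rounding, so
audible material at segment edges is never dropped at the cost of at most
one extra frame per edge.

## Stage 1 — spatially constrained tissue classification

**Variance seeding.** The ROI seed is the set of pixels whose temporal
population variance (divisor = frame count) exceeds the `quantile`-th
quantile of the variance map, strictly. Default quantile 0.75; it is a
coarse net, deliberately — the analyst's polygon edits, not the quantile,
define the final ROI. Additions are rasterised first, then removals, so
removals win on overlap; every edit is appended to the ROI's provenance
list.

**Threshold.** Intensities of all ROI pixels pooled across all frames of
the run feed a Gaussian KDE (Silverman bandwidth) evaluated on a 512-point
grid. The grid extends 3 bandwidths beyond the observed range on each
side: with noise-free data the air and tissue values are point masses at
the extremes of the range, and a peak at a grid endpoint is invisible to
local-maximum detection. Pooling all frames (rather than one reference
frame) maximises the sample and yields the single per-run threshold the
workflow expects. A local maximum counts as a mode only if its density
reaches 5% of the global maximum — enough to suppress noise wiggles without
hiding the air mode, which is genuinely smaller than the tissue mode. The
threshold is the minimum density between the two strongest modes; a flat
minimum resolves to the midpoint of the minimal plateau. If fewer than two
qualifying modes exist, `bimodality_ok` is False, a warning is raised, and
an Otsu threshold on the pooled sample is used so downstream stages remain
runnable while the analyst investigates. Classification is `ROI ∧
(intensity < threshold)`; a pixel exactly at the threshold is tissue, a
deterministic boundary rule.

## Stages 2–3 — selection and QA

Logged `[onset, offset]` intervals are inclusive on both ends and unioned
(overlap is not an error), preserving temporal order with each frame at
most once. The QA map is the per-pixel mean of the boolean series.
Exclusions operate on the classified masks, not the ROI, so Stage-1 outputs
stay reproducible; re-running Stage 1 with an edited ROI is the supported
alternative. Exclusion application is idempotent. The pink-overlay PNG is a
review aid; the numeric TIFF map is the canonical artifact.

## Stage 4 — A* bridging and outline tracing

The cost of stepping **into** pixel `p` is `(ε + Î(p)) · step_length`,
where `Î` is the frame intensity min–max normalised over the search region,
`step_length` is 1 axially and √2 diagonally, and `ε` (default 0.01) is the
floor cost per unit length. The normalised-intensity weight penalises
bright tissue so the walk follows dim pixels through constrictions; a
literal reciprocal weight would instead make dark air expensive and is not
what the method needs. `ε` keeps zero-intensity air traversable at a small
positive price and sets the length/brightness trade-off: at 0.01, crossing
one fully bright pixel costs as much as ~100 pixels of pure air, so the
connector crosses constrictions perpendicularly rather than wandering.
The heuristic `ε · Euclidean distance` never overestimates remaining cost
(every unit of distance costs at least `ε`), and is consistent, so the
returned path is globally optimal — the test suite checks equality with
scipy's Dijkstra and with exhaustive simple-path search. Determinism is
bit-level: fixed neighbour expansion order (N, NE, E, SE, S, SW, W, NW) and
a stable counter-tie-broken priority queue.

The search region is the ROI, not the frame's mask: a constriction is by
definition not in the mask, and the path must cross it through
analyst-approved space. Anchors are per-run inputs; absent those, the
fallback places the larynx at the most inferior mask pixel and the lips at
the most anterior one on the first non-empty frame (ties broken towards
smaller column, then smaller row).

Only frames with more than one cavity are bridged. Frames whose anchors
fall outside the frame mask or search region are skipped with a logged
reason; a run never aborts over one bad frame. If a connector leaves some
third cavity untouched, the component containing the larynx anchor is
traced and the status recorded.

Tracing fills interior holes first (the outer boundary is the object of
interest), then extracts the 0.5 iso-level contour by marching squares on
a zero-padded copy of the mask — sub-pixel, smooth enough for arc-length
resampling, and closed by construction. The contour is oriented to positive
shoelace area in `(y, z)` (clockwise as displayed with anterior to the
left of the image) and rotated to start at the contour point nearest the
lips anchor, ties resolved to the more superior point. Pixel-accurate
containment (true pixels inside, false pixels outside) is asserted against
a point-in-polygon oracle in the tests.

## Stage 5 — scripted correction

Site ranges are half-open `[start, stop)`. `erase` removes the range and
re-closes by joining the flanking points; `insert` splices after a site and
reverses the whole sequence if the splice flipped the signed-area sign (so
orientation is invariant across a set of outlines); `replace` composes the
two. Scripts are validated in full before any edit is applied
(all-or-nothing), and the audit log records the removed points for every
edit, which is exactly what `inverse_script` needs to build the undo
script. All edits are pure functions.

## Metrics

Dice is `2|X∩Y|/(|X|+|Y|)` on boolean grids of any rank; both-empty input
is an error, not a silent 0 or 1. Contours are compared after resampling to
a common number of equally arc-length-spaced sites, by linear interpolation
along the closed polyline starting from the shared start convention —
site correspondence across analysts rests entirely on that convention plus
arc-length position; no elastic registration is attempted, and because the
polyline is sampled directly (no smoothing basis is fitted first),
sub-pixel differences against function-based workflows are possible. The
default site count is the largest outline's point count. Disagreement at a
site is the mean Euclidean distance of each analyst's coordinate to the
group mean coordinate; the mm variant multiplies by the in-plane pixel
size, or scales each axis first when spacing is anisotropic. The identity
"identical contours → zero profile" holds to 1e-12 (a 3-way floating-point
mean can round by one ulp).

## Bias-field model

The field is estimated from a single reference image (temporal mean by
default — articulation and noise average out) in the log domain. Pixels
below the 10th intensity percentile are excluded: bias is a tissue-signal
phenomenon and the log of near-zero air values is unstable. The `gaussian`
model fits an order-2 polynomial surface to the valid log intensities,
smooths the residual with a large Gaussian kernel via normalized
convolution, and adds the trend back; the detrending step exists because a
finite smoothing kernel by itself attenuates any field that spans the whole
image, which breaks both the ≤5% recovery and the ≤2% re-estimation
flatness properties this module guarantees (both are asserted in the
tests). The `polynomial` model is the trend alone. Fields are normalised to
mean 1, so correction preserves overall image gain. Correction divides each
frame by the field and is strictly opt-in: whether it helps is a
per-dataset decision.

## Phantom generator

The phantom is an offset band of half-width `tube_width/2` around a cubic
spline through five control points, running from an anterior-superior
"lips" end to a posterior-inferior "larynx" end in a 64×64 frame — the
geometry of a midsagittal tract reduced to what the signal processing
actually sees: a dark curved corridor in bright surround. Tissue level 100,
air level 10 (strong T1 contrast); the tube width oscillates ±10% over the
run to mimic articulation (and to give the variance seeder something to
detect). Closures replace a 3-px arc-length span of the tube with tissue at
0.8 of the air→tissue contrast — a closed articulator is bulk tissue dimmed
only by partial-volume averaging at the contact surface; a much dimmer
closure would sit at the air/tissue density minimum and classify
unstably. Noise is additive Gaussian (magnitude-MRI noise is approximately
Gaussian at these SNRs; a Rician tail is not modelled) with negative
intensities clipped to zero; each frame's stream comes from an
independently spawned SeedSequence, so frame *k* is reproducible regardless
of run length. The bias stressor is a ±30% linear column ramp; the battery
pairs it with reduced contrast (air 60) because at 10:1 contrast a 30%
multiplicative ramp cannot entangle the two intensity modes and
classification would be unaffected — the reduced-contrast member is the
regime where inhomogeneity genuinely harms thresholding.

Ground truth: masks are the rasterised tube minus closure spans; outlines
are the 0.5-level contour of the truth mask (of the uninterrupted tube on
closure frames, since the ideal whole-tract outline encircles the closure);
anchors are the rounded centreline endpoints; the truth ROI is the tube's
temporal union dilated by 2 px.

What the phantom does **not** emulate: real anatomy (velum, epiglottis,
teeth, vertebrae), partial-volume blur at boundaries, Rician noise,
k-space/undersampling artefacts, or through-plane motion. Passing the
battery therefore demonstrates correct signal-processing behaviour under
controlled stressors, not segmentation accuracy on clinical data.

## Validation battery and problem sizes

`default_validation_suite` is fixed at five 64×64×50 members: clean, noisy
(σ = 10% of contrast), closure (frames 5–8 at mid-tube), bias (30% ramp,
reduced contrast), and combined (noise + closure + ramp). These sizes keep
the whole battery and its end-to-end pipeline runs in the order of seconds
while leaving every behaviour observable: tens of frames around a 4-frame
closure window, a tube a few hundred pixels in area, and pooled histograms
of ~30k samples for the KDE. `scripts/acceptance.py` re-runs everything
from a single seed.

## Known limitations

- One threshold per run: slow intensity drift *within* a run is not
  tracked (per-frame adaptive thresholds are out of scope).
- The A* connector is "biologically plausible", not guaranteed anatomical;
  the per-frame bridging report exists so analysts can audit it.
- The Otsu fallback on non-bimodal runs keeps the pipeline running but has
  no density-minimum interpretation; the warning should be treated as a
  data-quality flag.
- TextGrid support covers long-format interval tiers only.
- NIfTI metadata (fps, run id) travels in the 80-byte `descrip` header
  field; very long run identifiers are truncated.
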