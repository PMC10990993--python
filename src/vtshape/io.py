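"""Reading and writing of image stacks, logfiles, masks and outlines.

Supported stack formats
-----------------------
NIfTI (``.nii``/``.nii.gz``)
    Data are stored on disk as ``(row, col, frame)`` and transposed so that
    the in-memory frame axis is always first.  Pixel spacing round-trips
    through the header zooms; ``fps`` and ``run_id`` travel in the header
    ``descrip`` field as ``fps=<float>;run_id=<text>``.
multi-page TIFF (``.tif``/``.tiff``)
    One page per frame; metadata as a JSON ImageDescription tag.
raw array dump (``.npy``)
    A plain numpy array with a ``<file>.meta`` sidecar of ``key=value``
    lines (``fps``, ``pixel_mm``, ``run_id``).  A missing sidecar or a
    missing ``fps`` entry yields ``fps=nan`` with a warning, never an error.

Logfiles on disk use 1-based inclusive frame numbers (Praat/MATLAB
heritage); :func:`read_logfile` converts to the library's 0-based inclusive
convention exactly once.  TextGrid interval times are converted with
``onset = floor(t_start * fps)`` and ``offset = ceil(t_end * fps)`` (then
clamped), which never drops material at segment edges.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .errors import DimensionError, FormatError, ValidationError
from .types import FrameSelectionLog, ImageRun, Segment, TractMaskSeries, TractOutline

#: decimal places kept when outlines are serialised to CSV
OUTLINE_DECIMALS = 6

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _detect_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        hint = format_hint.lower()
        if hint in ("nifti", "nii"):
            return "nifti"
        if hint in ("tiff", "tif"):
            return "tiff"
        if hint in ("raw", "npy"):
            return "raw"
        raise FormatError(f"unknown format hint {format_hint!r}")
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        return "nifti"
    if sfx in _TIFF_SUFFIXES:
        return "tiff"
    if sfx == ".npy":
        return "raw"
    raise FormatError(f"cannot infer format from suffix {sfx!r} (tried NIfTI, TIFF, raw)")


def _descrip_encode(fps: float, run_id: str) -> bytes:
    # header field is 80 bytes; keep the run_id short enough to fit
    text = f"fps={fps};run_id={run_id}"
    return text.encode("ascii", "replace")[:79]

def _descrip_decode(raw: bytes) -> tuple[float, Optional[str]]:
    text = raw.decode("ascii", "replace").rstrip("\x00")
    m = re.search(r"fps=([^;]*)", text)
    fps = math.nan
    if m:
        try:
            fps = float(m.group(1))
        except ValueError:
            pass
    m = re.search(r"run_id=(.*)", text)
    run_id = m.group(1) if m else None
    return fps, run_id


def read_run(path, format_hint: Optional[str] = None) -> ImageRun:
    """Read an image stack as an :class:`~vtshape.types.ImageRun`.

    Parameters
    ----------
    path : path-like
        NIfTI, multi-page TIFF, or ``.npy`` raw dump with sidecar metadata.
    format_hint : str, optional
        Force a dialect (``"nifti"``, ``"tiff"`` or ``"raw"``) instead of
        inferring it from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "tiff":
        return _read_tiff(path)
    return _read_raw(path)


def _require_3d(data: np.ndarray, path: Path) -> None:
    if data.ndim == 2:
        raise DimensionError(
            f"{path} holds a single 2-D image; a dynamic run needs a (frame, row, col) stack"
        )
    if data.ndim != 3:
        raise DimensionError(f"{path}: expected 3-D data, got ndim={data.ndim}")


def _read_nifti(path: Path) -> ImageRun:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"{path} is not readable as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    _require_3d(data, path)
    zooms = img.header.get_zooms()
    pixel_mm = (float(zooms[0]), float(zooms[1]))
    fps, run_id = _descrip_decode(bytes(img.header["descrip"].tobytes()))
    if run_id is None:
        run_id = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    if math.isnan(fps):
        warnings.warn(f"{path}: no fps in header; using fps=nan", stacklevel=2)
    # disk layout is (row, col, frame)
    stack = np.transpose(data, (2, 0, 1)).astype(np.float64)
    return ImageRun(stack, fps=fps, pixel_mm=pixel_mm, run_id=run_id)


def write_run(run: ImageRun, path) -> Path:
    """Persist a run; the dialect follows the file suffix."""
    path = Path(path)
    fmt = _detect_format(path, None)
    if fmt == "nifti":
        data = np.transpose(run.intensities, (1, 2, 0))
        img = nib.Nifti1Image(data, affine=np.diag([run.pixel_mm[0], run.pixel_mm[1], 1.0, 1.0]))
        img.header.set_zooms((run.pixel_mm[0], run.pixel_mm[1], 1.0))
        img.header["descrip"] = _descrip_encode(run.fps, run.run_id)
        nib.save(img, str(path))
    elif fmt == "tiff":
        meta = {"fps": run.fps, "pixel_mm": list(run.pixel_mm), "run_id": run.run_id}
        tifffile.imwrite(
            path,
            run.intensities.astype(np.float64),
            photometric="minisblack",
            description=json.dumps(meta),
        )
    else:
        np.save(path, run.intensities)
        lines = [
            f"fps={run.fps}",
            f"pixel_mm={run.pixel_mm[0]},{run.pixel_mm[1]}",
            f"run_id={run.run_id}",
        ]
        Path(str(path) + ".meta").write_text("\n".join(lines) + "\n")
    return path


def _read_tiff(path: Path) -> ImageRun:
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
    except Exception as exc:
        raise FormatError(f"{path} is not readable as TIFF: {exc}") from exc
    _require_3d(data, path)
    fps, pixel_mm, run_id = math.nan, (1.0, 1.0), path.stem
    if desc:
        try:
            meta = json.loads(desc)
            fps = float(meta.get("fps", math.nan))
            if "pixel_mm" in meta:
                pixel_mm = (float(meta["pixel_mm"][0]), float(meta["pixel_mm"][1]))
            run_id = str(meta.get("run_id", run_id))
        except (json.JSONDecodeError, TypeError, KeyError):
            pass
    if math.isnan(fps):
        warnings.warn(f"{path}: no fps metadata; using fps=nan", stacklevel=2)
    return ImageRun(data.astype(np.float64), fps=fps, pixel_mm=pixel_mm, run_id=run_id)


def _read_raw(path: Path) -> ImageRun:
    try:
        data = np.load(path, allow_pickle=False)
    except Exception as exc:
        raise FormatError(f"{path} is not readable as a raw numpy dump: {exc}") from exc
    _require_3d(data, path)
    fps, pixel_mm, run_id = math.nan, (1.0, 1.0), path.stem
    sidecar = Path(str(path) + ".meta")
    if sidecar.exists():
        kv = {}
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                kv[k.strip()] = v.strip()
        if "fps" in kv:
            try:
                fps = float(kv["fps"])
            except ValueError:
                pass
        if "pixel_mm" in kv:
            parts = kv["pixel_mm"].split(",")
            pixel_mm = (float(parts[0]), float(parts[1]))
        run_id = kv.get("run_id", run_id)
    if math.isnan(fps):
        warnings.warn(f"{path}: no fps metadata found; using fps=nan", stacklevel=2)
    return ImageRun(data.astype(np.float64), fps=fps, pixel_mm=pixel_mm, run_id=run_id)


# ---------------------------------------------------------------------------
# frame-selection logfiles
# ---------------------------------------------------------------------------

def read_logfile(
    path,
    fps: Optional[float] = None,
    n_frames: Optional[int] = None,
    tier: Optional[str] = None,
) -> FrameSelectionLog:
    """Read a frame-selection log from CSV or a Praat TextGrid.

    CSV files need a header with ``onset,offset,label`` columns and 1-based
    inclusive integer frame numbers; the result is 0-based inclusive.  For a
    TextGrid, ``fps`` is required to convert interval times to frames; only
    intervals with a non-empty label are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".textgrid":
        if fps is None or not math.isfinite(fps) or fps <= 0:
            raise ValidationError("TextGrid conversion requires a finite positive fps")
        return _read_textgrid(path, fps, n_frames, tier)
    return _read_logfile_csv(path, n_frames)


def _read_logfile_csv(path: Path, n_frames: Optional[int]) -> FrameSelectionLog:
    try:
        df = pd.read_csv(path, dtype={"label": str})
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = {"onset", "offset"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    segments = []
    for i, row in df.iterrows():
        onset, offset = row["onset"], row["offset"]
        for name, v in (("onset", onset), ("offset", offset)):
            if float(v) != int(float(v)):
                raise FormatError(f"{path} row {i}: non-integer {name} frame {v!r}")
        onset, offset = int(onset), int(offset)
        if onset > offset:
            raise ValidationError(f"{path} row {i}: onset {onset} > offset {offset}")
        if onset < 1:
            raise ValidationError(f"{path} row {i}: frame numbers are 1-based; got onset {onset}")
        label = "" if "label" not in df.columns or pd.isna(row.get("label")) else str(row["label"])
        segments.append(Segment(onset - 1, offset - 1, label))
    log = FrameSelectionLog(segments)
    _check_bounds(log, n_frames, path)
    return log


def _check_bounds(log: FrameSelectionLog, n_frames: Optional[int], path: Path) -> None:
    if n_frames is None:
        return
    for i, s in enumerate(log.segments):
        if s.offset >= n_frames:
            raise ValidationError(
                f"{path} segment {i} ({s.label!r}): offset frame {s.offset} outside run of {n_frames} frames"
            )


_TG_INTERVAL = re.compile(
    r"intervals\s*\[\d+\]\s*:?\s*"
    r"xmin\s*=\s*([\d.eE+-]+)\s*"
    r"xmax\s*=\s*([\d.eE+-]+)\s*"
    r'text\s*=\s*"((?:[^"]|"")*)"',
)
_TG_TIER = re.compile(r'item\s*\[\d+\]\s*:\s*class\s*=\s*"(\w+)"\s*name\s*=\s*"((?:[^"]|"")*)"')


def _read_textgrid(path: Path, fps: float, n_frames: Optional[int], tier: Optional[str]) -> FrameSelectionLog:
    text = path.read_text(encoding="utf-8", errors="replace")
    tiers = list(_TG_TIER.finditer(text))
    if not tiers:
        raise FormatError(f"{path}: no tiers found (long-format TextGrid expected)")
    spans: list[tuple[str, str, str]] = []  # (class, name, body)
    for i, m in enumerate(tiers):
        end = tiers[i + 1].start() if i + 1 < len(tiers) else len(text)
        spans.append((m.group(1), m.group(2), text[m.end():end]))
    chosen = None
    for cls, name, body in spans:
        if cls != "IntervalTier":
            continue
        if tier is None or name == tier:
            chosen = body
            break
    if chosen is None:
        raise ValidationError(f"{path}: no interval tier" + (f" named {tier!r}" if tier else ""))
    segments = []
    for m in _TG_INTERVAL.finditer(chosen):
        t0, t1 = float(m.group(1)), float(m.group(2))
        label = m.group(3).replace('""', '"').strip()
        if not label:
            continue
        onset = int(math.floor(t0 * fps))
        offset = int(math.ceil(t1 * fps))
        if n_frames is not None:
            onset = min(max(onset, 0), n_frames - 1)
            offset = min(max(offset, 0), n_frames - 1)
        segments.append(Segment(onset, offset, label))
    return FrameSelectionLog(segments)


def write_logfile(log: FrameSelectionLog, path) -> Path:
    """Write a log back to CSV in the on-disk 1-based convention."""
    path = Path(path)
    df = pd.DataFrame(
        [(s.onset + 1, s.offset + 1, s.label) for s in log.segments],
        columns=["onset", "offset", "label"],
    )
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# mask series
# ---------------------------------------------------------------------------

def write_mask_series(masks: TractMaskSeries, path) -> Path:
    """Persist a boolean mask series losslessly as NIfTI uint8 or TIFF."""
    path = Path(path)
    fmt = _detect_format(path, None)
    data = masks.masks.astype(np.uint8)
    if fmt == "nifti":
        img = nib.Nifti1Image(np.transpose(data, (1, 2, 0)), affine=np.eye(4))
        nib.save(img, str(path))
    elif fmt == "tiff":
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        raise FormatError("mask series must be written as NIfTI or TIFF")
    return path


def read_mask_series(path) -> TractMaskSeries:
    """Read a mask series; any value other than 0/1 is a validation error."""
    path = Path(path)
    fmt = _detect_format(path, None)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        _require_3d(data, path)
        data = np.transpose(data, (2, 0, 1))
    elif fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
        _require_3d(data, path)
    else:
        raise FormatError("mask series must be NIfTI or TIFF")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError(f"{path}: mask file contains non-binary values {uniq[:5]}")
    return TractMaskSeries(data.astype(bool))


# ---------------------------------------------------------------------------
# outlines
# ---------------------------------------------------------------------------

def write_outlines(outlines: list[TractOutline], path, run_id: str = "") -> Path:
    """Write outlines to CSV (``run_id,frame,site_index,y,z``).

    Coordinates are written with :data:`OUTLINE_DECIMALS` decimal places, so
    a read-back reproduces them to that precision exactly.
    """
    if not outlines:
        raise ValidationError("refusing to write an empty outline list")
    path = Path(path)
    rows = []
    for outline in outlines:
        for i, (y, z) in enumerate(outline.points):
            rows.append((run_id, outline.frame, i, y, z))
    df = pd.DataFrame(rows, columns=["run_id", "frame", "site_index", "y", "z"])
    df.to_csv(path, index=False, float_format=f"%.{OUTLINE_DECIMALS}f")
    return path


def read_outlines(path) -> list[TractOutline]:
    """Read outlines written by :func:`write_outlines`, ordered by frame."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"frame", "site_index", "y", "z"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: outline CSV needs columns {sorted(required)}")
    outlines = []
    for frame, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("site_index")
        pts = grp[["y", "z"]].to_numpy(dtype=np.float64)
        outlines.append(TractOutline(pts, frame=int(frame)))
    return outlines
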