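"""Stage 5 — scriptable outline correction.

The interactive review stage (draw / erase / retrace) is replaced by a
declarative edit script so that analyst interventions are reproducible and
reviewable.  Site ranges are half-open ``[start, stop)`` over the outline's
point sequence; an ``erase`` removes the range and re-closes the outline,
an ``insert`` splices new points after a site, and a ``replace`` does both.
Application is validation-first and all-or-nothing, and the returned audit
log carries enough detail to construct the exact inverse script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .types import TractOutline


@dataclass
class Edit:
    frame: int
    action: str  # erase | insert | replace
    site_range: tuple[int, int]
    new_points: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.action not in ("erase", "insert", "replace"):
            raise ValidationError(f"unknown edit action {self.action!r}")
        a, b = self.site_range
        if a < 0 or b < a:
            raise ValidationError(f"invalid site range [{a}, {b})")
        if self.action in ("insert", "replace"):
            if self.new_points is None or len(np.atleast_2d(self.new_points)) == 0:
                raise ValidationError(f"{self.action} requires non-empty new_points")
            self.new_points = np.atleast_2d(np.asarray(self.new_points, dtype=np.float64))
            if not np.all(np.isfinite(self.new_points)):
                raise ValidationError("new_points must be finite")
        elif self.new_points is not None:
            raise ValidationError("erase carries no new_points")


@dataclass
class EditScript:
    edits: list[Edit] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: dict) -> "EditScript":
        edits = []
        for e in data.get("edits", []):
            rng = e.get("range", [0, 0])
            edits.append(
                Edit(
                    frame=int(e["frame"]),
                    action=str(e["action"]),
                    site_range=(int(rng[0]), int(rng[1])),
                    new_points=e.get("points"),
                )
            )
        return cls(edits)

    def to_dict(self) -> dict:
        out = []
        for e in self.edits:
            d = {"frame": e.frame, "action": e.action, "range": list(e.site_range)}
            if e.new_points is not None:
                d["points"] = e.new_points.tolist()
            out.append(d)
        return {"edits": out}


def _same_orientation(points: np.ndarray, reference_sign: float) -> np.ndarray:
    y, z = points[:, 0], points[:, 1]
    area = 0.5 * float(np.sum(y * np.roll(z, -1) - np.roll(y, -1) * z))
    if area != 0 and reference_sign != 0 and np.sign(area) != np.sign(reference_sign):
        return points[::-1].copy()
    return points


def erase_segment(outline: TractOutline, site_range: tuple[int, int]) -> TractOutline:
    """Remove sites in the half-open range and re-close the outline."""
    a, b = site_range
    n = outline.n_points
    if a < 0 or b < a or b > n:
        raise ValidationError(f"site range [{a}, {b}) invalid for an outline of {n} points")
    if b == a:
        return TractOutline(
            outline.points.copy(), outline.frame, outline.closed, outline.start_convention
        )
    if n - (b - a) < 3:
        raise ValidationError("erasing that range would leave fewer than 3 points")
    points = np.delete(outline.points, np.arange(a, b), axis=0)
    return TractOutline(points, outline.frame, outline.closed, outline.start_convention)


def insert_segment(
    outline: TractOutline, at_site: int, new_points: Sequence
) -> TractOutline:
    """Splice points after ``at_site``; orientation is preserved.

    If the splice flips the sign of the signed area, the whole sequence is
    reversed so every outline in a set keeps a consistent orientation.
    """
    pts = np.atleast_2d(np.asarray(new_points, dtype=np.float64))
    if pts.size == 0:
        raise ValidationError("new_points must be non-empty")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("new_points must be finite")
    n = outline.n_points
    if not -1 <= at_site < n:
        raise ValidationError(f"at_site {at_site} invalid for an outline of {n} points")
    merged = np.insert(outline.points, at_site + 1, pts, axis=0)
    merged = _same_orientation(merged, outline.signed_area())
    return TractOutline(merged, outline.frame, outline.closed, outline.start_convention)


def replace_segment(
    outline: TractOutline, site_range: tuple[int, int], new_points: Sequence
) -> TractOutline:
    """Retrace: erase the range, then insert the redrawn points in its place."""
    a, _ = site_range
    erased = erase_segment(outline, site_range)
    return insert_segment(erased, a - 1, new_points)


def apply_edit_script(
    outlines: list[TractOutline], script: EditScript
) -> tuple[list[TractOutline], list[dict]]:
    """Apply a correction session to a set of outlines, all-or-nothing.

    Every referenced frame must have an outline *before* any edit is
    applied.  Returns the edited outlines (unedited frames pass through
    untouched) and an audit log with one record per edit, including the
    removed points, so :func:`inverse_script` can undo the session.
    """
    by_frame = {o.frame: o for o in outlines}
    if len(by_frame) != len(outlines):
        raise ValidationError("duplicate frames in the outline list")
    missing = [e.frame for e in script.edits if e.frame not in by_frame]
    if missing:
        raise ValidationError(f"edit script references frames with no outline: {missing}")

    audit: list[dict] = []
    for i, e in enumerate(script.edits):
        before = by_frame[e.frame]
        a, b = e.site_range
        if e.action == "erase":
            removed = before.points[a:b].copy()
            after = erase_segment(before, e.site_range)
        elif e.action == "insert":
            removed = np.empty((0, 2))
            after = insert_segment(before, a - 1, e.new_points)
        else:  # replace
            removed = before.points[a:b].copy()
            after = replace_segment(before, e.site_range, e.new_points)
        by_frame[e.frame] = after
        audit.append(
            {
                "index": i,
                "frame": e.frame,
                "action": e.action,
                "range": [a, b],
                "removed_points": removed.tolist(),
                "inserted_points": e.new_points.tolist() if e.new_points is not None else [],
                "points_before": before.n_points,
                "points_after": after.n_points,
            }
        )
    return [by_frame[o.frame] for o in outlines], audit


def inverse_script(audit: list[dict]) -> EditScript:
    """Build the script that undoes an audited session (edits reversed)."""
    inverse: list[Edit] = []
    for rec in reversed(audit):
        a, b = rec["range"]
        removed = np.asarray(rec["removed_points"], dtype=np.float64).reshape(-1, 2)
        n_inserted = len(rec["inserted_points"])
        if rec["action"] == "erase":
            inverse.append(Edit(rec["frame"], "insert", (a, a), new_points=removed))
        elif rec["action"] == "insert":
            inverse.append(Edit(rec["frame"], "erase", (a, a + n_inserted)))
        else:
            inverse.append(Edit(rec["frame"], "replace", (a, a + n_inserted), new_points=removed))
    return EditScript(inverse)
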