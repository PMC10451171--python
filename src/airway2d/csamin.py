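"""Narrowest-row (CSAmin height) localisation from a label map.

The airway width at each level is taken as the number of airway pixels in
that image row.  The row with the minimum positive count within the searched
band is the predicted CSAmin height; it is reported in the native coordinate
frame, together with its segment (majority class of the row's airway
pixels).  Height errors convert to millimetres through the pixel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .imgio import (LabelMap, PIXEL_SPACING_MM, RETROGLOSSAL, RETROPALATAL,
                    SEGMENT_NAMES)

__all__ = [
    "WidthProfile",
    "CSAminResult",
    "width_profile",
    "locate_csamin",
    "assign_segment",
    "localize_csamin",
    "height_error",
    "px_to_mm",
]

AIRWAY_CLASSES = frozenset({1, 2, 3})


class NoAirwayError(ValueError):
    """Raised when the searched row range contains no airway pixels."""


@dataclass(frozen=True)
class WidthProfile:
    """Airway pixel count per image row."""

    counts: np.ndarray
    frame_height_px: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or len(counts) != self.frame_height_px:
            raise ValueError("counts length must equal frame height")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class CSAminResult:
    """Localised narrowest row, on the native frame, with its segment."""

    row_native: int
    row_frame: int
    width_px: int
    segment: str | None = None
    source: str = "prediction"


def width_profile(labels: LabelMap,
                  classes: Iterable[int] = AIRWAY_CLASSES) -> WidthProfile:
    """Count airway pixels (labels in ``classes``) in each row."""
    classes = set(classes)
    if not classes:
        raise ValueError("class set must be non-empty")
    if not classes <= AIRWAY_CLASSES:
        raise ValueError(f"classes must be within {{1,2,3}}, got {classes}")
    member = np.isin(labels.grid, sorted(classes))
    counts = member.sum(axis=1)
    return WidthProfile(counts=counts, frame_height_px=labels.grid.shape[0])


def _to_native(row_frame: int, frame_height: int, native_height: int) -> int:
    if frame_height == native_height:
        return int(row_frame)
    return int(round(row_frame * native_height / frame_height))


def locate_csamin(profile: WidthProfile,
                  search_rows: Sequence[int] | None = None,
                  tie_rule: str = "topmost",
                  native_height_px: int | None = None) -> CSAminResult:
    """Find the row with the minimum positive airway width.

    ``search_rows`` restricts the candidate rows (default: all rows);
    zero-count rows are excluded.  ``tie_rule='topmost'`` returns the
    smallest row index among minimisers, ``'bottommost'`` the largest.
    The row is mapped to the native frame when the profile was computed at
    reduced resolution.
    """
    if tie_rule not in ("topmost", "bottommost"):
        raise ValueError("tie_rule must be 'topmost' or 'bottommost'")
    counts = profile.counts
    if search_rows is None:
        rows = np.arange(len(counts))
    else:
        rows = np.asarray(list(search_rows), dtype=np.int64)
        if rows.size and (rows.min() < 0 or rows.max() >= len(counts)):
            raise ValueError("search rows outside the frame")
    rows = rows[counts[rows] > 0]
    if rows.size == 0:
        raise NoAirwayError("no airway pixels in the searched row range")
    vals = counts[rows]
    m = vals.min()
    minimisers = rows[vals == m]
    row = int(minimisers[0] if tie_rule == "topmost" else minimisers[-1])
    native = native_height_px if native_height_px is not None \
        else profile.frame_height_px
    return CSAminResult(
        row_native=_to_native(row, profile.frame_height_px, native),
        row_frame=row, width_px=int(m), segment=None,
    )


def assign_segment(labels: LabelMap, row: int) -> str:
    """Segment of a row: majority airway class, ties toward the more
    inferior (larger-id) class."""
    if not (0 <= row < labels.grid.shape[0]):
        raise ValueError(f"row {row} outside the frame")
    vals = labels.grid[row]
    counts = np.bincount(vals[vals > 0], minlength=4)[1:]
    if counts.sum() == 0:
        raise NoAirwayError(f"row {row} has no airway pixels")
    best = counts.max()
    cls = int(np.max(np.where(counts == best)[0]) + 1)
    return SEGMENT_NAMES[cls]


_SEGMENT_IDS = {v: k for k, v in SEGMENT_NAMES.items()}


def localize_csamin(labels: LabelMap,
                    search_segments: Sequence[str] = ("retropalatal",
                                                      "retroglossal"),
                    tie_rule: str = "topmost",
                    source: str = "prediction") -> CSAminResult:
    """Full localisation on a label map.

    The width profile counts all airway classes, but the search is
    restricted to rows containing pixels of the requested segments —
    by default the retropalatal + retroglossal band, where clinically
    relevant constrictions occur; pass all three segment names to widen
    the search to the nasopharynx.
    """
    ids = [_SEGMENT_IDS[s] for s in search_segments]
    profile = width_profile(labels)
    band = np.isin(labels.grid, ids).any(axis=1)
    res = locate_csamin(profile, search_rows=np.where(band)[0],
                        tie_rule=tie_rule,
                        native_height_px=labels.native_height_px)
    segment = assign_segment(labels, res.row_frame)
    return CSAminResult(row_native=res.row_native, row_frame=res.row_frame,
                        width_px=res.width_px, segment=segment, source=source)


def px_to_mm(l_px: float, pixel_spacing_mm: float = PIXEL_SPACING_MM) -> float:
    """Convert a pixel distance on the native frame to millimetres."""
    if l_px < 0:
        raise ValueError("pixel distance must be >= 0")
    return l_px * pixel_spacing_mm


def height_error(h_pred: int, h_ref: int,
                 pixel_spacing_mm: float = PIXEL_SPACING_MM
                 ) -> tuple[int, float]:
    """Absolute height error |h_pred - h_ref| in px and mm (native frame)."""
    l_px = abs(int(h_pred) - int(h_ref))
    return l_px, px_to_mm(l_px, pixel_spacing_mm)
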