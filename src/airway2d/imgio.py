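"""Image and fixture I/O.

Label maps are 2D integer grids with values 0-3 (0 background, 1 nasopharynx,
2 retropalatal pharynx, 3 retroglossal pharynx).  On disk they are stored as
indexed-colour PNGs using the conventional hues: red for the nasopharynx,
yellow for the retropalatal pharynx and green for the retroglossal pharynx.

Two small CSV fixtures ship with the package: a 2x2 contingency table of
CSAmin segment assignments (manual vs automatic) and a 40-subject table of
CSAmin heights and localisation errors.  Both are loaded with invariant
checks so that corruption is caught at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: Default in-plane pixel spacing in mm/px.  The native midsagittal captures
#: are 910 px across a 200 mm field of view, so one pixel is 200/910 mm; this
#: value reproduces every printed px -> mm error conversion in the packaged
#: height-error fixture after rounding to two decimals.
PIXEL_SPACING_MM = 200.0 / 910.0

#: Native (original-resolution) image height in pixels.
NATIVE_HEIGHT_PX = 910

NASOPHARYNX = 1
RETROPALATAL = 2
RETROGLOSSAL = 3

SEGMENT_NAMES = {
    NASOPHARYNX: "nasopharynx",
    RETROPALATAL: "retropalatal",
    RETROGLOSSAL: "retroglossal",
}

# Canonical label colours (RGB) for the indexed-colour PNG representation.
LABEL_COLOURS = {
    0: (0, 0, 0),
    NASOPHARYNX: (255, 0, 0),
    RETROPALATAL: (255, 255, 0),
    RETROGLOSSAL: (0, 255, 0),
}
_WHITE = (255, 255, 255)


class FormatError(ValueError):
    """Raised when an input file does not follow the expected convention."""


class FixtureError(RuntimeError):
    """Raised when a packaged data fixture fails its integrity checks."""


@dataclass
class LabelMap:
    """A 2D segment label grid with the metadata needed to map rows back to
    the native coordinate frame.

    Parameters
    ----------
    grid : ndarray of int
        2D array with values in {0, 1, 2, 3}.
    pixel_spacing_mm : float
        In-plane pixel size of the *native* frame, mm per pixel.
    native_height_px : int
        Height of the native frame; row indices found on a resized grid are
        mapped back to this frame before being reported.
    """

    grid: np.ndarray
    pixel_spacing_mm: float = PIXEL_SPACING_MM
    native_height_px: int = NATIVE_HEIGHT_PX

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("label grid must be a non-empty 2D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            if not np.all(self.grid == np.round(self.grid)):
                raise ValueError("label grid must contain integers")
            self.grid = self.grid.astype(np.int64)
        bad = set(np.unique(self.grid)) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"label values outside {{0,1,2,3}}: {sorted(bad)}")
        if self.native_height_px <= 0:
            raise ValueError("native_height_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.grid == class_id

    def with_grid(self, grid: np.ndarray) -> "LabelMap":
        return replace(self, grid=grid)


@dataclass(frozen=True)
class PairedHeights:
    """One subject's CSAmin heights (native-frame rows) and height errors.

    ``h_t`` is the manually determined reference height, ``h1`` the height
    found by the localiser on the manual segmentation and ``h2`` on the
    automatic segmentation; ``l1``/``l2`` are the absolute errors.
    """

    subject_id: int
    h_t: int
    h1: int
    h2: int
    l1_px: int
    l2_px: int
    l1_mm: float
    l2_mm: float

    def __post_init__(self) -> None:
        if self.l1_px != abs(self.h1 - self.h_t):
            raise FixtureError(
                f"subject {self.subject_id}: l1_px != |h1 - h_t|"
            )
        if self.l2_px != abs(self.h2 - self.h_t):
            raise FixtureError(
                f"subject {self.subject_id}: l2_px != |h2 - h_t|"
            )


@dataclass(frozen=True)
class ContingencyTable:
    """Square contingency table of segment assignments, raters in rows/cols."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ("retropalatal", "retroglossal")
    col_labels: tuple[str, ...] = ("retropalatal", "retroglossal")

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contingency table must be square")
        if np.any(self.counts < 0):
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# PNG I/O


def write_label_png(labels: LabelMap | np.ndarray, path: str | Path) -> None:
    """Write a label map as an indexed-colour PNG (black/red/yellow/green)."""
    grid = labels.grid if isinstance(labels, LabelMap) else np.asarray(labels)
    LabelMap(grid)  # validate
    img = Image.fromarray(grid.astype(np.uint8), mode="P")
    palette = [0] * 768
    for value, rgb in LABEL_COLOURS.items():
        palette[3 * value : 3 * value + 3] = rgb
    img.putpalette(palette)
    img.save(path, format="PNG")


def read_label_png(
    path: str | Path,
    colour_tolerance: int = 10,
    pixel_spacing_mm: float = PIXEL_SPACING_MM,
    native_height_px: int | None = None,
) -> LabelMap:
    """Read an indexed-colour or RGB label PNG into a :class:`LabelMap`.

    Pixels within ``colour_tolerance`` (per channel) of pure red, yellow or
    green map to classes 1, 2, 3; black and white map to background.  Any
    other colour raises :class:`FormatError` naming the offending colour.
    """
    with Image.open(path) as img:
        rgb = np.asarray(img.convert("RGB"), dtype=np.int16)
    grid = np.zeros(rgb.shape[:2], dtype=np.int64)
    matched = np.zeros(rgb.shape[:2], dtype=bool)
    for value, colour in [(0, LABEL_COLOURS[0]), (0, _WHITE)] + [
        (v, c) for v, c in LABEL_COLOURS.items() if v != 0
    ]:
        hit = np.all(np.abs(rgb - np.array(colour)) <= colour_tolerance, axis=-1)
        grid[hit & ~matched] = value
        matched |= hit
    if not matched.all():
        r, c = np.argwhere(~matched)[0]
        raise FormatError(
            f"unrecognised label colour {tuple(int(v) for v in rgb[r, c])} "
            f"at pixel (row={r}, col={c})"
        )
    if native_height_px is None:
        native_height_px = grid.shape[0]
    return LabelMap(grid, pixel_spacing_mm=pixel_spacing_mm,
                    native_height_px=native_height_px)


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    """Write a grayscale image with values in [0, 1] as an 8-bit PNG."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("image must be 2D")
    arr = np.clip(arr, 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(
        path, format="PNG"
    )


def read_image_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG into a float array in [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.float64)
    return arr / 255.0


# ---------------------------------------------------------------------------
# Packaged fixtures


def _fixture_path(name: str):
    return resources.files("airway2d.data").joinpath(name)


def load_table5() -> list[PairedHeights]:
    """Load the packaged 40-subject CSAmin height/error table."""
    with resources.as_file(_fixture_path("table5.csv")) as p:
        df = pd.read_csv(p)
    expected_cols = ["subject_id", "h_t", "h1", "h2",
                     "l1_px", "l2_px", "l1_mm", "l2_mm"]
    if list(df.columns) != expected_cols:
        raise FixtureError(f"unexpected columns {list(df.columns)}")
    if len(df) != 40:
        raise FixtureError(f"expected 40 subjects, found {len(df)}")
    records = [
        PairedHeights(
            subject_id=int(r.subject_id), h_t=int(r.h_t), h1=int(r.h1),
            h2=int(r.h2), l1_px=int(r.l1_px), l2_px=int(r.l2_px),
            l1_mm=float(r.l1_mm), l2_mm=float(r.l2_mm),
        )
        for r in df.itertuples()
    ]
    if [r.subject_id for r in records] != list(range(1, 41)):
        raise FixtureError("subject ids must be 1..40")
    return records


def table5_frame() -> pd.DataFrame:
    """The height/error fixture as a DataFrame (validated on load)."""
    records = load_table5()
    return pd.DataFrame([r.__dict__ for r in records])


def load_table4() -> ContingencyTable:
    """Load the packaged 2x2 CSAmin-segment contingency table."""
    with resources.as_file(_fixture_path("table4.csv")) as p:
        df = pd.read_csv(p)
    counts = df[["manual_retropalatal", "manual_retroglossal"]].to_numpy()
    table = ContingencyTable(counts)
    if table.total != 40:
        raise FixtureError(f"contingency total must be 40, got {table.total}")
    if list(df["ai_segment"]) != ["retropalatal", "retroglossal"]:
        raise FixtureError("unexpected row ordering in contingency fixture")
    return table
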