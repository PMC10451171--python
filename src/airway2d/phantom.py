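"""Synthetic midsagittal airway phantoms.

The phantom emulates the salient features of a 2D midsagittal radiographic
airway capture: a dark, roughly vertical air corridor on a brighter
soft-tissue background, split by row into three anatomical segments
(nasopharynx above, retropalatal pharynx in the middle, retroglossal pharynx
below), with a single dominant constriction whose row is known exactly.  The
constriction row is the ground truth that downstream CSAmin localisation has
to recover, standing in for a manually determined reference height.

A separate perturbation operator produces imperfect label maps — jittered
segment boundaries, false-positive blobs and false-negative holes — so the
morphological postprocessing and the localiser can be stressed without any
patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imgio import LabelMap, PIXEL_SPACING_MM

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "PerturbationSpec",
    "generate_phantom",
    "generate_dataset",
    "perturb_labels",
    "desk_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one phantom.

    Row indices follow raster order: row 0 is the top of the image.  The
    airway corridor spans ``airway_top_row``..``airway_bottom_row`` and the
    two ``segment_boundary_rows`` split that extent into the three segments.
    The corridor is strictly narrower at ``constriction_row`` than anywhere
    else, so the narrowest-row ground truth is unique by construction.
    """

    height_px: int = 910
    width_px: int = 910
    airway_top_row: int = 180
    airway_bottom_row: int = 780
    segment_boundary_rows: tuple[int, int] = (380, 560)
    centerline_amplitude_px: float = 25.0
    baseline_width_px: float = 60.0
    constriction_row: int = 650
    constriction_width_px: int = 12
    constriction_sigma_rows: float = 12.0
    background_intensity: float = 0.75
    airway_intensity: float = 0.15
    noise_sd: float = 0.05
    edge_blend_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        b0, b1 = self.segment_boundary_rows
        if not (0 <= self.airway_top_row < b0 < b1 < self.airway_bottom_row
                < self.height_px):
            raise ValueError(
                "segment ordering violated: require 0 <= airway_top_row < "
                "segment_boundary_rows[0] < segment_boundary_rows[1] < "
                "airway_bottom_row < height_px, got "
                f"airway_top_row={self.airway_top_row}, "
                f"segment_boundary_rows={self.segment_boundary_rows}, "
                f"airway_bottom_row={self.airway_bottom_row}"
            )
        if not (b0 <= self.constriction_row <= self.airway_bottom_row):
            raise ValueError(
                f"constriction_row={self.constriction_row} outside "
                f"[{b0}, {self.airway_bottom_row}]"
            )
        if self.constriction_width_px < 1:
            raise ValueError("constriction_width_px must be >= 1")
        if self.constriction_width_px >= self.baseline_width_px:
            raise ValueError(
                "constriction_width_px must be smaller than baseline_width_px"
            )
        for name in ("background_intensity", "airway_intensity", "noise_sd"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.width_px < 4 * self.baseline_width_px / 3:
            raise ValueError("width_px too small for the requested corridor")


@dataclass
class PhantomSample:
    """A generated phantom: image, ground-truth labels and true CSAmin row."""

    image: np.ndarray
    labels: LabelMap
    true_csamin_row: int


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled degradation of a label map, emulating an automatic
    segmentation: boundary jitter plus false-positive blobs and
    false-negative holes.  The all-zero spec is the identity.
    """

    boundary_jitter_sd_px: float = 0.0
    fp_blob_count: int = 0
    fn_hole_count: int = 0
    blob_area_px: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_sd_px < 0:
            raise ValueError("boundary_jitter_sd_px must be >= 0")
        if self.fp_blob_count < 0 or self.fn_hole_count < 0:
            raise ValueError("blob/hole counts must be >= 0")
        if self.blob_area_px < 1:
            raise ValueError("blob_area_px must be >= 1")

    @property
    def is_identity(self) -> bool:
        return (self.boundary_jitter_sd_px == 0
                and self.fp_blob_count == 0 and self.fn_hole_count == 0)


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  smooth_rows: float = 3.0) -> np.ndarray:
    """Row-correlated Gaussian noise with the requested marginal SD."""
    if sd == 0:
        return np.zeros(n)
    raw = rng.normal(size=n)
    sm = ndimage.gaussian_filter1d(raw, smooth_rows, mode="nearest")
    s = sm.std()
    if s == 0:
        return np.zeros(n)
    return sm * (sd / s)


def _integer_widths(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-row corridor width over the airway extent, in pixels.

    The profile is a smoothly varying baseline with a Gaussian notch at the
    constriction row.  After rounding, the constriction width is forced
    exactly and every other row is clamped to at least one pixel wider, so
    the row-count minimum is attained uniquely at the constriction.
    """
    rows = np.arange(spec.airway_top_row, spec.airway_bottom_row + 1)
    base = spec.baseline_width_px * (
        1.0 + 0.12 * np.sin(2 * np.pi * (rows - rows[0]) / max(len(rows), 1)
                            * 1.3 + rng.uniform(0, 2 * np.pi))
    )
    base = base + _smooth_noise(rng, len(rows), 0.05 * spec.baseline_width_px,
                                smooth_rows=15.0)
    notch = np.exp(-0.5 * ((rows - spec.constriction_row)
                           / spec.constriction_sigma_rows) ** 2)
    depth = base - spec.constriction_width_px
    widths = np.round(base - depth * notch).astype(int)
    i_con = spec.constriction_row - spec.airway_top_row
    widths = np.maximum(widths, spec.constriction_width_px + 1)
    widths[i_con] = spec.constriction_width_px
    return widths


def _centerline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    rows = np.arange(spec.airway_top_row, spec.airway_bottom_row + 1)
    phase = rng.uniform(0, 2 * np.pi)
    t = (rows - rows[0]) / max(len(rows) - 1, 1)
    c = (spec.width_px / 2.0
         + spec.centerline_amplitude_px * np.sin(2 * np.pi * 1.2 * t + phase))
    margin = spec.baseline_width_px * 0.8 + 2
    return np.clip(c, margin, spec.width_px - margin)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom image with its ground-truth label map.

    Deterministic for a fixed ``spec`` (including its seed).  The returned
    ``true_csamin_row`` is the unique row at which the airway pixel count is
    minimal over the corridor.
    """
    rng = np.random.default_rng(spec.seed)
    widths = _integer_widths(spec, rng)
    centers = _centerline(spec, rng)

    grid = np.zeros((spec.height_px, spec.width_px), dtype=np.int64)
    b0, b1 = spec.segment_boundary_rows
    for i, row in enumerate(range(spec.airway_top_row,
                                  spec.airway_bottom_row + 1)):
        w = int(widths[i])
        left = int(round(centers[i] - w / 2.0))
        left = max(0, min(left, spec.width_px - w))
        cls = 1 if row < b0 else (2 if row < b1 else 3)
        grid[row, left:left + w] = cls

    image = np.full(grid.shape, spec.background_intensity, dtype=np.float64)
    image[grid > 0] = spec.airway_intensity
    if spec.edge_blend_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.edge_blend_sigma)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    spacing = PIXEL_SPACING_MM * (910.0 / spec.height_px)
    labels = LabelMap(grid, pixel_spacing_mm=spacing,
                      native_height_px=spec.height_px)
    return PhantomSample(image=image, labels=labels,
                         true_csamin_row=spec.constriction_row)


def random_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Draw a geometry-jittered variant of ``base``.

    Segment boundary rows stay fixed (they are anatomical landmarks of the
    cohort the generator emulates); corridor shape, baseline width and the
    constriction row/width vary between samples.
    """
    b0 = base.segment_boundary_rows[0]
    lo = b0 + int(0.05 * base.height_px)
    hi = base.airway_bottom_row - int(0.03 * base.height_px)
    width_scale = rng.uniform(0.85, 1.15)
    cw = max(2, int(round(base.constriction_width_px * rng.uniform(0.75, 1.25))))
    return replace(
        base,
        baseline_width_px=base.baseline_width_px * width_scale,
        constriction_row=int(rng.integers(lo, hi + 1)),
        constriction_width_px=min(cw, int(base.baseline_width_px
                                          * width_scale) - 2),
        centerline_amplitude_px=base.centerline_amplitude_px
        * rng.uniform(0.5, 1.5),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(n: int, base: PhantomSpec | None = None,
                     seed: int = 0) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample geometry variation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base if base is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    return [generate_phantom(random_spec(base, rng)) for _ in range(n)]


def desk_spec(size: int = 96) -> PhantomSpec:
    """A reduced-resolution phantom preset for CPU-scale experiments.

    Geometry scales with ``size`` so the corridor remains several pixels
    wide; used by the desk-scale training profile.
    """
    s = size / 910.0
    return PhantomSpec(
        height_px=size,
        width_px=size,
        airway_top_row=max(2, int(180 * s)),
        airway_bottom_row=int(780 * s),
        segment_boundary_rows=(int(380 * s), int(560 * s)),
        centerline_amplitude_px=25.0 * s * 2,
        baseline_width_px=max(10.0, 140.0 * s),
        constriction_row=int(650 * s),
        constriction_width_px=max(3, int(46 * s)),
        constriction_sigma_rows=max(2.0, 12.0 * s * 2),
    )


# ---------------------------------------------------------------------------
# Perturbation


def _jitter_rows(grid: np.ndarray, sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Displace the left/right corridor edges by row-correlated noise.

    Operates row-wise on the foreground run of each row, preserving the
    row's class; suited to the single-corridor, row-banded maps the phantom
    produces.
    """
    out = np.zeros_like(grid)
    fg_rows = np.where((grid > 0).any(axis=1))[0]
    if fg_rows.size == 0 or sd == 0:
        return grid.copy()
    n = grid.shape[0]
    dl = np.round(_smooth_noise(rng, n, sd)).astype(int)
    dr = np.round(_smooth_noise(rng, n, sd)).astype(int)
    W = grid.shape[1]
    for r in fg_rows:
        cols = np.where(grid[r] > 0)[0]
        left, right = cols[0] + dl[r], cols[-1] + dr[r]
        left = int(np.clip(left, 0, W - 1))
        right = int(np.clip(right, 0, W - 1))
        if right < left:
            left = right = (left + right) // 2
        counts = np.bincount(grid[r][cols], minlength=4)
        cls = int(np.argmax(counts[1:]) + 1)
        out[r, left:right + 1] = cls
    return out


def _disk_offsets(area: int) -> np.ndarray:
    """Offsets of the ``area`` pixels nearest the origin (a rounded disk)."""
    r = int(np.ceil(np.sqrt(area))) + 1
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d = yy**2 + xx**2
    order = np.argsort(d.ravel(), kind="stable")[:area]
    return np.stack([yy.ravel()[order], xx.ravel()[order]], axis=1)


def perturb_labels(labels: LabelMap, pspec: PerturbationSpec) -> LabelMap:
    """Degrade a label map per ``pspec``; identity for the all-zero spec.

    False-positive blobs (``fp_blob_count`` components of exactly
    ``blob_area_px`` pixels) are placed outside the original foreground with
    a 2-px clearance, labelled with the class of the nearest foreground
    pixel.  False-negative holes of the same area are carved out of the
    foreground.  Deterministic for a fixed spec.
    """
    if pspec.is_identity:
        return labels.with_grid(labels.grid.copy())
    rng = np.random.default_rng(pspec.seed)
    grid = _jitter_rows(labels.grid, pspec.boundary_jitter_sd_px, rng)
    orig_fg = labels.grid > 0
    H, W = grid.shape

    # false-negative holes
    fg_idx = np.argwhere(grid > 0)
    for _ in range(pspec.fn_hole_count):
        if fg_idx.size == 0:
            break
        cy, cx = fg_idx[rng.integers(len(fg_idx))]
        for dy, dx in _disk_offsets(pspec.blob_area_px):
            y, x = cy + dy, cx + dx
            if 0 <= y < H and 0 <= x < W:
                grid[y, x] = 0

    # false-positive blobs, kept clear of the foreground and of each other
    if pspec.fp_blob_count > 0:
        _, nearest = ndimage.distance_transform_edt(~orig_fg,
                                                    return_indices=True)
        occupied = ndimage.binary_dilation(grid > 0, iterations=3)
        placed = 0
        attempts = 0
        offs = _disk_offsets(pspec.blob_area_px)
        pad = int(np.abs(offs).max()) + 3
        while placed < pspec.fp_blob_count and attempts < 10000:
            attempts += 1
            cy = int(rng.integers(pad, H - pad))
            cx = int(rng.integers(pad, W - pad))
            ys, xs = offs[:, 0] + cy, offs[:, 1] + cx
            region = occupied[cy - pad:cy + pad + 1, cx - pad:cx + pad + 1]
            if region.any():
                continue
            src_y, src_x = nearest[0][cy, cx], nearest[1][cy, cx]
            cls = int(labels.grid[src_y, src_x])
            if cls == 0:
                cls = 2
            grid[ys, xs] = cls
            occupied[max(0, cy - pad):cy + pad + 1,
                     max(0, cx - pad):cx + pad + 1] = True
            placed += 1
        if placed < pspec.fp_blob_count:
            raise RuntimeError("could not place all false-positive blobs")
    return labels.with_grid(grid)
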