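"""Image loading, enhancement and paired-ROI handling for B-mode liver scans.

The enhancement chain mirrors standard B-ultrasound practice: convert to an
8-bit gray image, suppress speckle with a small median filter, enlarge the
gray dynamic range (percentile contrast stretch, or histogram equalization),
and optionally binarize for visual quality control.  Regions of interest come
in pairs: a rectangle inside the lesion (A1) and a same-depth reference
rectangle in normal parenchyma (A2); placement is manual and this module only
validates the pairing rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage import exposure

from .errors import DegenerateInputError, DimensionError, GeometryError, ParameterError

#: Default physical size of one pixel.  At 0.1 mm the canonical 1x1 cm
#: analysis window is 100x100 pixels.
DEFAULT_PIXEL_SPACING_MM = 0.1

#: Side of the canonical analysis window in millimetres.
ANALYSIS_WINDOW_MM = 10.0

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale image with pixel-spacing metadata.

    Parameters
    ----------
    pixels
        2-D integer array with values in ``[0, 255]``.
    pixel_spacing_mm
        Physical side of one pixel in millimetres (isotropic).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DimensionError(f"expected a 2-D pixel grid, got ndim={px.ndim}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise DimensionError(f"image must be at least 8x8, got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.pixel_spacing_mm <= 0:
            raise ParameterError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open ``[row0, row1) x [col0, col1)``, 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise GeometryError(f"empty rectangle {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    @property
    def center_row(self) -> float:
        return (self.row0 + self.row1) / 2.0

    def inside(self, img: GrayImage) -> bool:
        return (
            self.row0 >= 0
            and self.col0 >= 0
            and self.row1 <= img.height
            and self.col1 <= img.width
        )

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.row0 < other.row1
            and other.row0 < self.row1
            and self.col0 < other.col1
            and other.col0 < self.col1
        )


@dataclass(frozen=True)
class RoiPair:
    """Lesion rectangle (A1) and same-depth normal reference rectangle (A2)."""

    a1: Rect
    a2: Rect


def to_grayscale(image: np.ndarray, pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM) -> GrayImage:
    """Convert a 2-D or channels-last RGB array to an 8-bit :class:`GrayImage`.

    RGB input is reduced with the ITU-R BT.601 luminance weights
    (0.299, 0.587, 0.114), rounded to the nearest integer and clipped to
    ``[0, 255]``; 2-D input passes through unchanged.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[-1] == 3:
        gray = np.rint(arr.astype(float) @ _LUMA_WEIGHTS)
    else:
        raise DimensionError(
            f"expected 2-D or (H, W, 3) input, got shape {arr.shape}"
        )
    gray = np.clip(gray, 0, 255)
    return GrayImage(gray, pixel_spacing_mm=pixel_spacing_mm)


def stretch_contrast(img: GrayImage, lo_pct: float = 1.0, hi_pct: float = 99.0) -> GrayImage:
    """Linearly map the ``lo_pct``/``hi_pct`` intensity percentiles to 0/255.

    Values outside the percentile window are clipped.  A constant image is
    returned unchanged (there is no range to enlarge).
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ParameterError(f"require 0 <= lo_pct < hi_pct <= 100, got ({lo_pct}, {hi_pct})")
    px = img.pixels.astype(float)
    lo, hi = np.percentile(px, [lo_pct, hi_pct])
    if hi <= lo:  # constant (or near-constant within the window)
        return img
    out = np.clip(np.rint((px - lo) * 255.0 / (hi - lo)), 0, 255)
    return replace(img, pixels=out)


def equalize_histogram(img: GrayImage) -> GrayImage:
    """Histogram equalization, the alternative reading of gray-range enlargement."""
    eq = exposure.equalize_hist(img.pixels, nbins=256)
    return replace(img, pixels=np.rint(eq * 255.0))


def despeckle(img: GrayImage, kernel: int = 3) -> GrayImage:
    """Median filter with reflective borders; the default 3x3 kernel is the
    standard speckle-robust choice."""
    if kernel % 2 == 0 or kernel < 3:
        raise ParameterError(f"kernel must be odd and >= 3, got {kernel}")
    if kernel > min(img.height, img.width):
        raise ParameterError("kernel larger than image")
    out = ndimage.median_filter(img.pixels, size=kernel, mode="reflect")
    return replace(img, pixels=out)


def binarize(img: GrayImage) -> np.ndarray:
    """Otsu-threshold mask (``intensity > t``); QC only, never used for features."""
    px = img.pixels
    if px.min() == px.max():
        raise DegenerateInputError("cannot binarize a constant image")
    t = threshold_otsu(px)
    return px > t


def min_window_side_px(img: GrayImage) -> int:
    """Pixels needed per side for one 1x1 cm analysis window at this spacing."""
    return int(round(ANALYSIS_WINDOW_MM / img.pixel_spacing_mm))


def validate_roi_pair(img: GrayImage, pair: RoiPair, depth_tol: float = 10.0) -> list[str]:
    """Check the A1/A2 pairing rules; returns the names of violated rules.

    Rules: (``"overlap"``) the rectangles must be disjoint; (``"depth"``) their
    row centers must agree within ``depth_tol`` pixels, the linear-probe
    reading of "same depth"; (``"size"``) each side must fit at least one
    1x1 cm analysis window.
    """
    for name, rect in (("a1", pair.a1), ("a2", pair.a2)):
        if not rect.inside(img):
            raise GeometryError(f"{name} rectangle {rect} outside image {img.shape}")
    violations: list[str] = []
    if pair.a1.overlaps(pair.a2):
        violations.append("overlap")
    if abs(pair.a1.center_row - pair.a2.center_row) > depth_tol:
        violations.append("depth")
    need = min_window_side_px(img)
    for rect in (pair.a1, pair.a2):
        if rect.height < need or rect.width < need:
            violations.append("size")
            break
    return violations


def extract_roi(img: GrayImage, rect: Rect) -> GrayImage:
    """Crop ``rect`` out of ``img``; pixel spacing metadata is preserved."""
    if not rect.inside(img):
        raise GeometryError(f"rectangle {rect} outside image {img.shape}")
    return replace(img, pixels=img.pixels[rect.row0 : rect.row1, rect.col0 : rect.col1])
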