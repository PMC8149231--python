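"""Fixed-order 30-feature vector per ROI.

Each ROI is tiled into non-overlapping 1x1 cm analysis windows (100x100 px at
the default 0.1 mm spacing); the ROI's feature vector is the mean over its
windows.  The column layout, fixed and documented here, is:

* 18 GLCM statistics: offsets (d=1, theta in {0,45,90,135}) and
  (d=2, theta in {0,90}), each contributing entropy, ASM and contrast —
  columns ``glcm_d{d}_a{theta}_{stat}``;
* 3 Fourier ring energies ``fourier_ring_1..3`` (equal-width radial bands of
  the power spectrum, DC removed);
* 9 wavelet-fractal components ``mf_3_0 .. mf_1_6``.

For the fractal components each window is center-cropped to 96x96 so the
hybrid decomposition's size constraints are met; GLCM and Fourier features
use the full window.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import GeometryError
from .fractal import FRACTAL_FEATURE_NAMES, fractal_feature_vector
from .preprocess import GrayImage, Rect, extract_roi, min_window_side_px
from .texture import compute_glcm, fourier_ring_energies, glcm_stats

GLCM_OFFSETS = ((1, 0), (1, 45), (1, 90), (1, 135), (2, 0), (2, 90))
GLCM_STAT_NAMES = ("entropy", "asm", "contrast")
N_FOURIER_RINGS = 3
GLCM_LEVELS = 32

#: Side (px) of the crop fed to the wavelet-fractal stage: the largest
#: multiple of 8 inside a 100 px window.
FRACTAL_CROP_SIDE = 96

GLCM_FEATURE_NAMES = tuple(
    f"glcm_d{d}_a{a}_{stat}" for (d, a) in GLCM_OFFSETS for stat in GLCM_STAT_NAMES
)
FOURIER_FEATURE_NAMES = tuple(f"fourier_ring_{i + 1}" for i in range(N_FOURIER_RINGS))

#: The documented fixed order of the 30 feature columns.
FEATURE_NAMES: tuple[str, ...] = GLCM_FEATURE_NAMES + FOURIER_FEATURE_NAMES + FRACTAL_FEATURE_NAMES

assert len(FEATURE_NAMES) == 30


def window_features(window: GrayImage) -> np.ndarray:
    """30-feature vector of a single square analysis window."""
    values: list[float] = []
    for d, a in GLCM_OFFSETS:
        s = glcm_stats(compute_glcm(window, d=d, theta=a, levels=GLCM_LEVELS))
        values.extend((s.entropy, s.asm, s.contrast))
    ff = fourier_ring_energies(window, n_rings=N_FOURIER_RINGS)
    values.extend(ff.ring_energies)

    side = min(window.shape)
    crop = min(FRACTAL_CROP_SIDE, (side // 8) * 8)
    r0 = (window.height - crop) // 2
    c0 = (window.width - crop) // 2
    fr_win = replace(window, pixels=window.pixels[r0 : r0 + crop, c0 : c0 + crop])
    values.extend(fractal_feature_vector(fr_win))
    return np.array(values)


def tile_windows(roi: GrayImage) -> list[GrayImage]:
    """Non-overlapping 1x1 cm windows inside the ROI, raster order."""
    side = min_window_side_px(roi)
    n_r, n_c = roi.height // side, roi.width // side
    if n_r == 0 or n_c == 0:
        raise GeometryError(
            f"ROI {roi.shape} smaller than one {side}x{side} analysis window"
        )
    return [
        replace(roi, pixels=roi.pixels[i * side : (i + 1) * side, j * side : (j + 1) * side])
        for i in range(n_r)
        for j in range(n_c)
    ]


def roi_features(roi: GrayImage) -> np.ndarray:
    """Mean 30-feature vector over the ROI's analysis windows."""
    return np.mean([window_features(w) for w in tile_windows(roi)], axis=0)


def extract_feature_table(
    images: list[GrayImage],
    rois: list[Rect] | None = None,
    labels: list | None = None,
) -> pd.DataFrame:
    """Feature rows (one per image/ROI) with the documented column order."""
    rows = []
    for k, img in enumerate(images):
        roi = extract_roi(img, rois[k]) if rois is not None else img
        rows.append(roi_features(roi))
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        df["label"] = list(labels)
    return df
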