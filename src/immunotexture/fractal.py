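"""Hybrid 2-/3-channel wavelet decomposition and fractal texture features.

The intensity surface of a textured window is treated as a fractal: its
dimension ``D_f`` lies between 2 (smooth plane) and 3 (space filling) and
grows with roughness.  ``D_f`` is estimated by differential box counting
(DBC): the image is tiled by ``s x s`` columns of boxes of height
``s * 256 / side`` and the number of boxes needed to cover the min..max
intensity span is accumulated per scale; the fractal dimension is the
least-squares slope of ``log N(s)`` versus ``log(1/r)`` with ``r = s / side``.

The multiresolution feature vector ``MF`` has nine components:

=====  =============================================================
index  subimage
=====  =============================================================
0      the raw window itself
1      LL of a 2-channel (Haar) separable split
2      LH of the same split (low-pass rows, high-pass columns)
3..8   six of the nine subbands of a 3-channel split of LH
=====  =============================================================

The 3-channel stage is an orthonormal three-point block transform applied
separably (filters ~ [1,1,1], [1,0,-1], [1,-2,1], normalized); of its 3x3
subband grid the six retained bands are those whose column filter is not the
low-pass, taken in raster order.  Detail-band dimensions of the LH band are
the components reported to discriminate cirrhosis from carcinoma textures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import GeometryError
from .preprocess import GrayImage

# Orthonormal 3-channel analysis filters (low, band, high), applied as a
# non-overlapping 3x3 block transform along both axes.
_G3 = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, 0.0, -1.0],
        [1.0, -2.0, 1.0],
    ]
) / np.sqrt([[3.0], [2.0], [6.0]])

#: (row-filter, col-filter) indices of the six level-2 bands used by MF,
#: raster order over the 3x3 grid excluding the column-lowpass bands.
LEVEL2_BANDS = ((0, 1), (0, 2), (1, 1), (1, 2), (2, 1), (2, 2))


@dataclass(frozen=True)
class SubbandTree:
    """Subimages of the hybrid decomposition, keyed by (level, name)."""

    original: np.ndarray
    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    level2: dict[tuple[int, int], np.ndarray]  # keyed by (row-filter, col-filter)


def _haar_split(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    # pywt returns (cA, (cH, cV, cD)): cH = rows high-pass (vertical detail).
    # Our LH = low-pass along rows (ordinate), high-pass along columns, i.e.
    # horizontal detail = cV in pywt's naming.
    ca, (ch, cv, cd) = pywt.dwt2(x, "haar")
    return ca, cv, ch, cd  # LL, LH, HL, HH


def _three_band_split(x: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Separable 3-channel block transform; input cropped to a multiple of 3."""
    n = (min(x.shape) // 3) * 3
    x = x[:n, :n]
    blocks = x.reshape(n // 3, 3, n // 3, 3)
    # transform rows (axis 1) and columns (axis 3) of each 3x3 block
    coef = np.einsum("pu,qv,aubv->pqab", _G3, _G3, blocks)
    return {(p, q): coef[p, q] for p in range(3) for q in range(3)}


def hybrid_decompose(window: GrayImage) -> SubbandTree:
    """Two-level hybrid split: 2-channel Haar, then 3-channel on the LH band."""
    px = np.asarray(window.pixels, dtype=float)
    h, w = px.shape
    if h != w:
        raise GeometryError(f"window must be square, got {px.shape}")
    if h < 64 or h % 8 != 0:
        raise GeometryError(f"side must be >= 64 and divisible by 8, got {h}")
    ll, lh, hl, hh = _haar_split(px)
    level2 = _three_band_split(lh)
    return SubbandTree(original=px, ll=ll, lh=lh, hl=hl, hh=hh, level2=level2)


def fractal_dimension(sub: np.ndarray) -> float:
    """Differential box-counting dimension of an intensity surface.

    The grid is linearly rescaled to [0, 255] so box-height quantization is
    consistent across subbands; a constant grid is a flat surface and returns
    exactly 2.0.  The estimate is clipped to the admissible surface range
    [2.0, 3.0].
    """
    z = np.asarray(sub, dtype=float)
    side = min(z.shape)
    if side < 8:
        raise GeometryError(f"grid side must be >= 8, got {z.shape}")
    z = z[:side, :side]
    zmin, zmax = z.min(), z.max()
    if zmax <= zmin:
        return 2.0
    z = (z - zmin) * (255.0 / (zmax - zmin))

    # powers of two from 2 to side/4, but always at least two scales so the
    # log-log slope is defined on small (>= 8 px) subbands
    sizes = []
    s = 2
    while s <= max(side // 4, 4):
        sizes.append(s)
        s *= 2
    log_inv_r, log_n = [], []
    for s in sizes:
        m = (side // s) * s
        blocks = z[:m, :m].reshape(m // s, s, m // s, s)
        bmax = blocks.max(axis=(1, 3))
        bmin = blocks.min(axis=(1, 3))
        height = s * 256.0 / side  # box height keeps boxes cubic in scaled units
        n_boxes = np.ceil((bmax - bmin + 1.0) / height)
        log_inv_r.append(np.log(side / s))
        log_n.append(np.log(n_boxes.sum()))
    slope = np.polyfit(log_inv_r, log_n, 1)[0]
    return float(np.clip(slope, 2.0, 3.0))


def fractal_feature_vector(window: GrayImage) -> np.ndarray:
    """Nine-component multiresolution fractal vector MF.

    Order: raw window, LL, LH, then the six level-2 subbands of LH in the
    fixed :data:`LEVEL2_BANDS` raster order.
    """
    tree = hybrid_decompose(window)
    mf = [
        fractal_dimension(tree.original),
        fractal_dimension(tree.ll),
        fractal_dimension(tree.lh),
    ]
    mf.extend(fractal_dimension(tree.level2[band]) for band in LEVEL2_BANDS)
    return np.array(mf)


FRACTAL_FEATURE_NAMES = (
    "mf_3_0",
    "mf_2_1",
    "mf_2_2",
    "mf_1_1",
    "mf_1_2",
    "mf_1_3",
    "mf_1_4",
    "mf_1_5",
    "mf_1_6",
)
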