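"""Gray-level cooccurrence and Fourier spectrum texture features.

A GLCM ``P(a, b)`` holds the joint probability that two pixels separated by a
fixed displacement (distance ``d`` pixels, direction ``theta`` degrees) take
quantized gray levels ``a`` and ``b``.  Pair counting is symmetric
(unordered), the common convention, and the raw pair count ``T`` is retained
so the convention is auditable.  From the normalized matrix we compute

* entropy  ``H = -sum P log2 P``      (texture complexity, in bits),
* angular second moment  ``ASM = sum P^2``  (gray-distribution uniformity),
* contrast  ``sum (a - b)^2 P(a, b)``   (local intensity variation).

The Fourier energy spectrum descriptor partitions the centered 2-D power
spectrum (DC removed) into equal-width concentric rings and reports the
fraction of energy per ring — low rings capture coarse structure, high rings
fine speckle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .preprocess import GrayImage

SUPPORTED_ANGLES = (0, 45, 90, 135)
SUPPORTED_LEVELS = (8, 16, 32, 64)

# (row, col) displacement per angle, at unit distance.  0 deg is horizontal
# (along a scan line); angles grow counter-clockwise with rows pointing down.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class Glcm:
    """Normalized gray-level cooccurrence matrix for one (distance, angle)."""

    matrix: np.ndarray  # levels x levels, sums to 1
    levels: int
    distance: int
    angle: int
    pair_count: int  # raw symmetric pair count T before normalization

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.levels, self.levels):
            raise ValueError(f"matrix shape {m.shape} != levels {self.levels}")
        if (m < 0).any():
            raise ValueError("GLCM entries must be nonnegative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must be normalized to sum 1")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class GlcmStats:
    entropy: float
    asm: float
    contrast: float


@dataclass(frozen=True)
class FourierFeatures:
    ring_energies: np.ndarray  # normalized, sums to 1 (or all zero if constant)
    total_energy: float


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit intensities to ``levels`` equal-width bins over [0, 255]."""
    return (pixels.astype(np.int64) * levels) // 256


def compute_glcm(window: GrayImage, d: int = 1, theta: int = 0, levels: int = 32) -> Glcm:
    """Symmetric GLCM of ``window`` at displacement ``(d, theta)``.

    Intensities are first quantized to ``levels`` equal-width bins.  Every
    ordered pixel pair at the displacement is counted in both orders, so the
    matrix is symmetric and ``pair_count`` is twice the number of unordered
    pairs.
    """
    if theta not in SUPPORTED_ANGLES:
        raise ValueError(f"angle must be one of {SUPPORTED_ANGLES}, got {theta}")
    if levels not in SUPPORTED_LEVELS:
        raise ValueError(f"levels must be one of {SUPPORTED_LEVELS}, got {levels}")
    if d < 1:
        raise ValueError("distance must be >= 1")
    q = quantize(window.pixels, levels)
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    if h <= abs(dr) or w <= abs(dc):
        raise GeometryError(
            f"window {q.shape} too small for offset ({dr}, {dc})"
        )
    # Overlapping views of the two members of each ordered pair.
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T  # symmetric (unordered) counting
    t = int(counts.sum())
    return Glcm(matrix=counts / t, levels=levels, distance=d, angle=theta, pair_count=t)


def glcm_entropy(g: Glcm) -> float:
    """Shannon entropy of the GLCM in bits; 0 iff a single nonzero entry."""
    p = g.matrix[g.matrix > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_asm(g: Glcm) -> float:
    """Angular second moment (energy): sum of squared entries, in (0, 1]."""
    return float((g.matrix**2).sum())


def glcm_contrast(g: Glcm) -> float:
    """Inertia: ``sum (a-b)^2 P(a,b)`` over quantized level indices."""
    idx = np.arange(g.levels)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float((diff2 * g.matrix).sum())


def glcm_stats(g: Glcm) -> GlcmStats:
    return GlcmStats(entropy=glcm_entropy(g), asm=glcm_asm(g), contrast=glcm_contrast(g))


def fourier_ring_energies(window: GrayImage, n_rings: int = 4) -> FourierFeatures:
    """Radial partition of the 2-D power spectrum into ``n_rings`` bands.

    The spectrum is centered, the DC term removed, and each ring's energy is
    normalized by the total; a constant window returns an all-zero vector.
    """
    px = np.asarray(window.pixels, dtype=float)
    h, w = px.shape
    if h != w:
        raise GeometryError(f"window must be square, got {px.shape}")
    if h < 2 * n_rings:
        raise GeometryError(f"side {h} < 2 * n_rings ({n_rings})")
    spec = np.fft.fftshift(np.abs(np.fft.fft2(px)) ** 2)
    cy, cx = h // 2, w // 2
    spec[cy, cx] = 0.0  # remove DC
    yy, xx = np.indices(spec.shape)
    radius = np.hypot(yy - cy, xx - cx)
    r_max = h / 2.0
    ring = np.minimum((radius / (r_max / n_rings)).astype(int), n_rings - 1)
    total = float(spec.sum())
    if total <= 0.0:
        return FourierFeatures(ring_energies=np.zeros(n_rings), total_energy=0.0)
    energies = np.bincount(ring.ravel(), weights=spec.ravel(), minlength=n_rings)
    return FourierFeatures(ring_energies=energies / total, total_energy=total)
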