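"""Synthetic B-mode speckle textures for the three liver tissue classes.

No public image archive exists for this task, so every stage of the pipeline
is exercised on simulated speckle.  The model is fully developed speckle: a
complex circular-Gaussian scatterer field, low-pass filtered at the class's
speckle correlation length, whose envelope magnitude is Rayleigh-distributed.
The envelope is modulated by a slow multiplicative gain field (tissue
heterogeneity) and mapped linearly onto the class's gray-level range.

The three default recipes encode the qualitative sonographic axes of the
tissue classes — normal parenchyma: fine, dense, uniform speckle; cirrhosis:
coarser, unevenly distributed echoes; carcinoma: irregular texture with a
hypoechoic lesion and a widened gray-level range — as increasing correlation
length, heterogeneity amplitude and gray range.  The classes are constructed
to be learnable but not trivially separable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .classifiers import LabeledDataset, assign_folds
from .errors import ParameterError
from .features import FEATURE_NAMES, roi_features
from .preprocess import DEFAULT_PIXEL_SPACING_MM, GrayImage, despeckle, stretch_contrast

CLASS_NAMES = ("normal", "cirrhosis", "cancer")


@dataclass(frozen=True)
class ClassRecipe:
    """Generator parameters for one tissue class.

    Parameters
    ----------
    label
        Class name.
    correlation_length
        Speckle grain size in pixels (Gaussian low-pass sigma of the
        scatterer field); larger means coarser texture.
    scatterer_density
        Relative density of sub-resolution scatterers; scales the complex
        field variance (brightness before gray mapping).
    heterogeneity
        Amplitude of the slow multiplicative gain field (0 = perfectly
        uniform parenchyma).
    gray_lo, gray_hi
        Target gray-level range of the rendered image.
    lesion
        Whether to embed an irregular hypoechoic lesion blob.
    """

    label: str
    correlation_length: float
    scatterer_density: float = 1.0
    heterogeneity: float = 0.0
    gray_lo: int = 0
    gray_hi: int = 255
    lesion: bool = False

    def __post_init__(self) -> None:
        if self.correlation_length < 1.0:
            raise ParameterError("correlation_length must be >= 1 pixel")
        if self.heterogeneity < 0 or self.scatterer_density <= 0:
            raise ParameterError("amplitudes must be nonnegative")


#: Default study recipes: coarseness, heterogeneity and gray range increase
#: from normal to cirrhosis to cancer.
DEFAULT_RECIPES: dict[str, ClassRecipe] = {
    "normal": ClassRecipe(
        label="normal", correlation_length=1.0, heterogeneity=0.05, gray_lo=20, gray_hi=200
    ),
    "cirrhosis": ClassRecipe(
        label="cirrhosis", correlation_length=2.2, heterogeneity=0.35, gray_lo=10, gray_hi=225
    ),
    "cancer": ClassRecipe(
        label="cancer",
        correlation_length=2.6,
        heterogeneity=0.45,
        gray_lo=0,
        gray_hi=255,
        lesion=True,
    ),
}

#: Slow gain-field scale (pixels); much longer than any speckle grain.
_GAIN_SIGMA = 48.0

#: Relative per-image jitter of recipe parameters (biological variability):
#: log-normal sigma for correlation length and heterogeneity, additive
#: gray-bound jitter in intensity units.
_JITTER_CORR = 0.12
_JITTER_HET = 0.18
_JITTER_GRAY = 8.0


def _jitter_recipe(recipe: ClassRecipe, rng: np.random.Generator) -> ClassRecipe:
    """Per-image variation around the class recipe; classes overlap but keep
    their ordering on average."""
    lo = recipe.gray_lo + rng.normal(0, _JITTER_GRAY)
    hi = recipe.gray_hi + rng.normal(0, _JITTER_GRAY)
    lo = int(np.clip(lo, 0, 100))
    hi = int(np.clip(hi, lo + 64, 255))
    return ClassRecipe(
        label=recipe.label,
        correlation_length=max(1.0, recipe.correlation_length * rng.lognormal(0, _JITTER_CORR)),
        scatterer_density=recipe.scatterer_density,
        heterogeneity=recipe.heterogeneity * rng.lognormal(0, _JITTER_HET),
        gray_lo=lo,
        gray_hi=hi,
        lesion=recipe.lesion,
    )


def _lesion_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """Irregular blob covering roughly a quarter of the image."""
    base = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 8.0)
    yy, xx = np.indices((size, size))
    cy, cx = size / 2 + rng.uniform(-size / 8, size / 8, 2)
    dist = np.hypot(yy - cy, xx - cx) / (0.30 * size)
    field = base / base.std() - 2.0 * (dist - 1.0)
    return field > 0


def generate_speckle_image(
    recipe: ClassRecipe,
    size: int = 256,
    seed: int | np.random.Generator = 0,
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM,
) -> GrayImage:
    """Render one seeded speckle image for ``recipe``.

    The complex scatterer field stays Gaussian under low-pass filtering, so
    the envelope remains Rayleigh-distributed at any correlation length; only
    the spatial grain changes.
    """
    if size < 128:
        raise ParameterError("size must be >= 128")
    rng = np.random.default_rng(seed)
    field = rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))
    field = ndimage.gaussian_filter(field.real, recipe.correlation_length) + 1j * ndimage.gaussian_filter(
        field.imag, recipe.correlation_length
    )
    envelope = np.abs(field) * np.sqrt(recipe.scatterer_density)

    if recipe.heterogeneity > 0:
        gain = ndimage.gaussian_filter(rng.standard_normal((size, size)), _GAIN_SIGMA)
        gain = 1.0 + recipe.heterogeneity * gain / gain.std()
        envelope = envelope * np.clip(gain, 0.1, None)

    if recipe.lesion:
        mask = _lesion_mask(size, rng)
        envelope = np.where(mask, 0.45 * envelope, envelope)  # hypoechoic blob

    # map the envelope onto the class gray range; the 99.9th percentile sets
    # the top so a few bright scatterers do not compress the whole histogram
    top = np.percentile(envelope, 99.9)
    px = recipe.gray_lo + (recipe.gray_hi - recipe.gray_lo) * np.clip(envelope / top, 0, 1)
    return GrayImage(np.rint(px), pixel_spacing_mm=pixel_spacing_mm)


def fractional_brownian_surface(size: int, hurst: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Spectral synthesis of an isotropic fBm surface with Hurst exponent H.

    Power spectrum ~ f^-(2H+2); the theoretical surface fractal dimension is
    ``3 - H``.  Used for calibrating the box-counting estimator.
    """
    if not 0 < hurst < 1:
        raise ParameterError("hurst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    amp = f ** (-(hurst + 1.0))
    amp[0, 0] = 0.0
    phase = rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))
    return np.real(np.fft.ifft2(amp * phase))


def default_preprocess(img: GrayImage) -> GrayImage:
    """The standard enhancement chain applied before feature extraction."""
    return stretch_contrast(despeckle(img, kernel=3), 1.0, 99.0)


def generate_dataset(
    n_per_class: int = 100,
    recipes: dict[str, ClassRecipe] | None = None,
    seed: int = 0,
    size: int = 256,
    out_dir: str | Path | None = None,
    preprocess: bool = True,
) -> LabeledDataset:
    """Balanced labeled feature dataset with stratified 5-fold assignments.

    The default 100 images per class mirrors the study design (300 samples:
    100 normal, 100 cirrhosis, 100 carcinoma).  Images are optionally written
    to ``out_dir`` as PNGs together with a ROI config YAML and features.csv.
    """
    if n_per_class < 5:
        raise ParameterError("need at least 5 images per class for 5 folds")
    recipes = recipes or DEFAULT_RECIPES
    rng = np.random.default_rng(seed)
    rows, labels, images, names = [], [], [], []
    for label in CLASS_NAMES:
        recipe = recipes[label]
        for k in range(n_per_class):
            img = generate_speckle_image(_jitter_recipe(recipe, rng), size=size, seed=rng)
            if preprocess:
                img = default_preprocess(img)
            rows.append(roi_features(img))
            labels.append(label)
            images.append(img)
            names.append(f"{label}_{k:03d}.png")
    features = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    fold_id = assign_folds(np.asarray(labels), n_folds=5, seed=seed)
    data = LabeledDataset(features=features, labels=np.asarray(labels), fold_id=fold_id)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio

        half = size // 2
        roi_cfg = {}
        for name, img in zip(names, images):
            iio.imwrite(out / name, img.pixels)
            roi_cfg[name] = {
                "a1": [0, 0, half, size],
                "a2": [half, 0, size, size],
            }
        with open(out / "rois.yaml", "w") as fh:
            yaml.safe_dump(roi_cfg, fh)
        table = features.copy()
        table["label"] = labels
        table["fold_id"] = fold_id
        table.to_csv(out / "features.csv", index=False)
    return data
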