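"""Color-space primitives shared by every pipeline stage.

Images are plain ``numpy`` arrays by convention, not wrapper classes:

* an RGB image is ``uint8`` of shape ``(H, W, 3)``;
* an HSV image is ``float64`` of shape ``(H, W, 3)`` with hue stored as a
  fraction of the full circle in ``[0, 1)`` (not degrees) so that channel-wise
  maxima are comparable across the three planes, and S, V in ``[0, 1]``;
* a specular-reflection (SR) mask is ``bool`` of shape ``(H, W)`` — True
  marks region Ω (to be repaired), False the known region Φ.

The conversions are the standard hexcone HSV and the sRGB/D65 CIE XYZ
transform; the nonlinear chromaticity enhancement and the luminance /
chromatic-luminance pair used for SR thresholding live here because both the
global and local detectors build on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "MIN_SIDE",
    "DegenerateInputError",
    "LuminanceField",
    "validate_rgb",
    "validate_mask",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "luminance_fields",
    "chroma_enhance",
]

#: Minimum side length accepted at pipeline entry.
MIN_SIDE = 16


class DegenerateInputError(ValueError):
    """Raised for inputs on which a quantity is mathematically undefined
    (e.g. the chromatic luminance of an all-black image)."""


def validate_rgb(img: np.ndarray, *, min_side: int | None = None) -> np.ndarray:
    """Check that *img* is an 8-bit H×W×3 RGB raster and return it.

    ``min_side`` (default: no constraint) enforces the pipeline-entry minimum
    when set; pass :data:`MIN_SIDE` at pipeline boundaries.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise ValueError(f"expected dtype uint8, got {img.dtype}")
    if min_side is not None and min(img.shape[:2]) < min_side:
        raise ValueError(
            f"image sides must be >= {min_side}, got {img.shape[0]}x{img.shape[1]}"
        )
    return img


def validate_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Check that *mask* is a boolean H×W map (optionally of given shape)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected an H x W mask, got shape {mask.shape}")
    if mask.dtype != bool:
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask values must be binary")
        mask = mask.astype(bool)
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match image shape {tuple(shape)}")
    return mask


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Standard hexcone RGB→HSV; hue of achromatic pixels is 0."""
    img = validate_rgb(img)
    return _skcolor.rgb2hsv(img)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse hexcone conversion with round-to-nearest 8-bit quantization.

    Exact inverse of :func:`rgb_to_hsv`: the round trip reproduces any 8-bit
    image bit-for-bit.
    """
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 HSV image, got shape {hsv.shape}")
    rgb = _skcolor.hsv2rgb(hsv)
    return np.rint(rgb * 255.0).astype(np.uint8)


# CIE Y is invariant under the validation above; keep XYZ private to this module.
def _xyz(img: np.ndarray) -> np.ndarray:
    return _skcolor.rgb2xyz(img)  # sRGB linearization + D65 matrix


@dataclass(frozen=True)
class LuminanceField:
    """Per-pixel luminance and the image-level chromatic luminance.

    Attributes
    ----------
    y_pixel : (H, W) float64
        CIE Y of each pixel under the sRGB/D65 transform, in [0, 1].
    y_global : float
        Chromatic luminance of the whole image, ΣY / (ΣX + ΣY + ΣZ), a
        dimensionless ratio in (0, 1).  Being a chromaticity it is invariant
        to uniform intensity scaling, which is what makes ``y >= ω·y_global``
        a usable relative-brightness test.
    """

    y_pixel: np.ndarray
    y_global: float


def luminance_fields(img: np.ndarray) -> LuminanceField:
    """Compute the luminance pair compared by the SR detectors.

    Raises :class:`DegenerateInputError` on an all-black image, for which the
    chromaticity ratio is 0/0.
    """
    img = validate_rgb(img)
    xyz = _xyz(img)
    denom = float(xyz.sum())
    if denom == 0.0:
        raise DegenerateInputError("y_global undefined for an all-black image")
    return LuminanceField(y_pixel=xyz[..., 1], y_global=float(xyz[..., 1].sum()) / denom)


def chroma_enhance(img: np.ndarray) -> np.ndarray:
    """Nonlinear chromaticity enhancement: scale each pixel by min/max.

    Every pixel (R, G, B) becomes (min/max)·(R, G, B), i.e. a per-pixel gain
    of ``1 − S``.  Saturated (chromatic) pixels are strongly dimmed while the
    near-achromatic, high-brightness specular pixels pass through almost
    unchanged, widening the gap the luminance threshold then exploits.
    Achromatic pixels are exactly unchanged; an all-zero (black) pixel has an
    undefined 0/0 gain and is defined to map to itself.
    """
    img = validate_rgb(img)
    f = img.astype(np.float64)
    mx = f.max(axis=2)
    mn = f.min(axis=2)
    scale = np.divide(mn, mx, out=np.ones_like(mx), where=mx > 0)
    return np.rint(f * scale[..., None]).astype(np.uint8)
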