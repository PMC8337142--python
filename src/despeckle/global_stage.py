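"""Stage 1 — global specular-highlight detection and smooth repair.

Detection runs on the luminance channel in two modules, after the
colonoscopy approach of Arnold: an absolute threshold catches significantly
strong highlights, and a softer threshold restricted to low-saturation
pixels, cross-checked against a median-filtered background (relative
contrast), catches the slightly non-strong ones.  Because acetowhite (AW)
tissue shares the whitish chromaticity of specular spots but forms much
larger patches, connected components above an area fraction are dropped
unless their peak luminance is extreme.

Repair replaces each detected component with the mean color of a ring of
surrounding non-specular pixels, smooths the filled image with a wide
Gaussian (σ = 8 by default), and blends the smoothed image back into the
original under a mask with Gaussian falloff outside the detected region —
so pixels far from any highlight are returned bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .color import DegenerateInputError, luminance_fields, rgb_to_hsv, validate_mask, validate_rgb
from .exemplar import UnrepairableMaskError

__all__ = [
    "GlobalParams",
    "detect_global",
    "centroid_fill",
    "gaussian_smooth",
    "build_blend_mask",
    "run_global_stage",
]

_STRUCT8 = np.ones((3, 3), bool)  # 8-connectivity


@dataclass(frozen=True)
class GlobalParams:
    """Thresholds and repair parameters of the global stage.

    Luminance thresholds are on normalized CIE Y in [0, 1]; none of the
    defaults comes from a published table — they encode "small, very bright,
    nearly unsaturated spots" and are meant to be tuned per acquisition
    setup via the config file.
    """

    t_abs: float = 0.92          # absolute threshold, strong-highlight module
    t_soft: float = 0.85         # soft threshold of the slightly-nonstrong module
    s_max: float = 0.12          # saturation ceiling for soft candidates
    bg_window: int = 31          # median window for background estimation (odd)
    rel_factor: float = 1.35     # relative contrast ratio against background
    max_area_frac: float = 0.015  # components larger than this fraction = AW, dropped
    peak_override: float = 0.98  # ...unless their peak luminance reaches this
    sigma: float = 8.0           # Gaussian smoothing width of the repair
    ring_width: int = 3          # sampling ring radius for the centroid fill
    falloff_sigma: float = 4.0   # Gaussian falloff of the blend mask
    cutoff: float = 12.0         # blend support radius (weights 0 beyond)

    def __post_init__(self) -> None:
        if not (0.0 < self.t_soft < self.t_abs <= 1.0):
            raise ValueError("need 0 < t_soft < t_abs <= 1")
        if not (0.0 <= self.s_max <= 1.0):
            raise ValueError("s_max must lie in [0, 1]")
        if self.bg_window < 1 or self.bg_window % 2 == 0:
            raise ValueError("bg_window must be a positive odd integer")
        if self.rel_factor <= 1.0:
            raise ValueError("rel_factor must exceed 1")
        if not (0.0 < self.max_area_frac < 1.0):
            raise ValueError("max_area_frac must lie in (0, 1)")
        if self.sigma <= 0 or self.falloff_sigma <= 0 or self.cutoff <= 0:
            raise ValueError("sigma, falloff_sigma and cutoff must be positive")
        if self.ring_width < 1:
            raise ValueError("ring_width must be >= 1")


def detect_global(img: np.ndarray, params: GlobalParams | None = None) -> np.ndarray:
    """Two-module luminance detection with AW size/brightness limiting.

    Returns a boolean H×W mask: the union of absolute-threshold pixels and
    soft low-saturation pixels that also pass the relative contrast test,
    with oversized components removed unless their peak luminance reaches
    ``peak_override``.
    """
    img = validate_rgb(img)
    params = params or GlobalParams()
    try:
        y = luminance_fields(img).y_pixel
    except DegenerateInputError:
        return np.zeros(img.shape[:2], bool)
    sat = rgb_to_hsv(img)[..., 1]

    strong = y >= params.t_abs
    soft = (y >= params.t_soft) & (sat <= params.s_max)
    background = ndimage.median_filter(y, size=params.bg_window, mode="reflect")
    contrast = y >= params.rel_factor * background
    mask = strong | (soft & contrast)

    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n:
        max_area = params.max_area_frac * mask.size
        areas = ndimage.sum_labels(np.ones_like(y), labels, index=np.arange(1, n + 1))
        peaks = ndimage.maximum(y, labels, index=np.arange(1, n + 1))
        drop = (areas > max_area) & (peaks < params.peak_override)
        if drop.any():
            mask &= ~np.isin(labels, np.nonzero(drop)[0] + 1)
    return mask


def centroid_fill(img: np.ndarray, mask: np.ndarray, ring_width: int = 3) -> np.ndarray:
    """Fill each connected masked component with its surround's mean color.

    The fill color of a component is the arithmetic mean RGB over the ring
    of non-masked pixels within Chebyshev distance ``ring_width`` of the
    component.  Raises :class:`UnrepairableMaskError` when a component has
    no non-masked pixel in its ring (e.g. the mask covers the image).
    """
    img = validate_rgb(img)
    mask = validate_mask(mask, img.shape[:2])
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    out = img.copy()
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    for i in range(1, n + 1):
        comp = labels == i
        ring = ndimage.binary_dilation(comp, _STRUCT8, iterations=ring_width) & ~mask
        if not ring.any():
            raise UnrepairableMaskError(
                "masked component has no non-masked neighborhood to sample from"
            )
        color = np.rint(img[ring].mean(axis=0)).astype(np.uint8)
        out[comp] = color
    return out


def gaussian_smooth(img: np.ndarray, sigma: float = 8.0) -> np.ndarray:
    """Per-channel Gaussian blur, reflective borders, kernel radius ⌈3σ⌉."""
    img = validate_rgb(img)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = int(np.ceil(3.0 * sigma))
    out = np.empty_like(img, dtype=np.float64)
    for ch in range(3):
        out[..., ch] = ndimage.gaussian_filter(
            img[..., ch].astype(np.float64), sigma, mode="reflect", radius=radius
        )
    return np.rint(out).astype(np.uint8)


def build_blend_mask(
    mask: np.ndarray, falloff_sigma: float = 4.0, cutoff: float = 12.0
) -> np.ndarray:
    """Weight field: 1 on Ω, Gaussian decay with Euclidean distance, 0 past cutoff."""
    mask = validate_mask(mask)
    if falloff_sigma <= 0 or cutoff <= 0:
        raise ValueError("falloff_sigma and cutoff must be positive")
    if not mask.any():
        return np.zeros(mask.shape, np.float64)
    d = ndimage.distance_transform_edt(~mask)
    w = np.exp(-(d**2) / (2.0 * falloff_sigma**2))
    w[d > cutoff] = 0.0
    w[mask] = 1.0
    return w


def run_global_stage(
    img: np.ndarray, params: GlobalParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect, fill, smooth and blend; returns (repaired image, mask).

    The output equals ``w·smooth(fill(img)) + (1−w)·img`` per channel with
    8-bit rounding; pixels with zero blend weight are bit-identical to the
    input.
    """
    img = validate_rgb(img)
    params = params or GlobalParams()
    mask = detect_global(img, params)
    if not mask.any():
        return img.copy(), mask
    filled = centroid_fill(img, mask, params.ring_width)
    smoothed = gaussian_smooth(filled, params.sigma)
    w = build_blend_mask(mask, params.falloff_sigma, params.cutoff)[..., None]
    blended = np.rint(w * smoothed.astype(np.float64) + (1.0 - w) * img.astype(np.float64))
    out = np.where(w > 0, blended, img).astype(np.uint8)
    return out, mask
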