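"""Stage 3 — merge the globally-smoothed and locally-textured repairs.

Both repaired images are converted to HSV and combined per pixel by taking
the channel-wise maximum of (H, S, V); the merged HSV image is converted
back to 8-bit RGB.  Taking the larger V keeps the brighter of the two
repairs and slightly raises light/shade contrast; taking the larger S keeps
the more saturated (more tissue-like) of the two.  Hue is a circular
quantity stored here as a fraction in [0, 1), and the default mode
maximizes it literally as a scalar; ``hue_mode='dominant_v'`` instead takes
the hue of whichever input is brighter at that pixel, for users who prefer
a circularity-safe merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import hsv_to_rgb, rgb_to_hsv, validate_rgb

__all__ = ["IntegrationResult", "integrate"]


@dataclass(frozen=True)
class IntegrationResult:
    image: np.ndarray    # final 8-bit RGB output
    hsv_new: np.ndarray  # merged HSV planes before re-quantization


def integrate(
    global_img: np.ndarray, local_img: np.ndarray, hue_mode: str = "literal_max"
) -> IntegrationResult:
    """Per-pixel HSV maximum of the two stage outputs.

    The merge is commutative and, because the HSV round trip is bit-exact,
    idempotent: integrating an image with itself returns it unchanged.
    """
    global_img = validate_rgb(global_img)
    local_img = validate_rgb(local_img)
    if global_img.shape != local_img.shape:
        raise ValueError(
            f"shape mismatch: {global_img.shape} vs {local_img.shape}"
        )
    if hue_mode not in ("literal_max", "dominant_v"):
        raise ValueError("hue_mode must be 'literal_max' or 'dominant_v'")
    hsv_g = rgb_to_hsv(global_img)
    hsv_l = rgb_to_hsv(local_img)
    hsv_new = np.maximum(hsv_g, hsv_l)
    if hue_mode == "dominant_v":
        local_brighter = hsv_l[..., 2] > hsv_g[..., 2]
        hsv_new[..., 0] = np.where(local_brighter, hsv_l[..., 0], hsv_g[..., 0])
    return IntegrationResult(image=hsv_to_rgb(hsv_new), hsv_new=hsv_new)
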