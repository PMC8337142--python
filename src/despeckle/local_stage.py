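"""Stage 2 — block-wise detection and exemplar repair.

The image is tiled into k×k near-equal rectangles and each block is treated
independently: the block is chromaticity-enhanced (each pixel scaled by
min/max, which dims colored tissue but leaves near-white highlights alone),
and pixels whose CIE luminance reaches ω times the enhanced block's chromatic
luminance Y/(X+Y+Z) are flagged as specular.  Blocks with an empty mask are
copied verbatim; flagged blocks are repaired by the exemplar engine with the
patch search confined to the block, which keeps the texture statistics of
the fill local.  The coefficient ω ≥ 1 shrinks the detection as it grows —
the local stage deliberately targets the larger highlights and leaves
pinpoint speckle to the global stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .color import DegenerateInputError, chroma_enhance, luminance_fields, validate_rgb
from .exemplar import NoSourceError, inpaint

__all__ = ["BlockGrid", "LocalParams", "make_grid", "detect_local", "run_local_stage"]

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class LocalParams:
    """Local-detection parameters.

    omega
        Multiplier ω ≥ 1 on the chromatic luminance threshold (default 1.2).
    dilate_px
        Chebyshev radius of the mask dilation applied before inpainting, so
        the fill overwrites the dim halo ringing each highlight (default 2).
    y_global_scope
        'block' computes the reference chromatic luminance per block
        (default); 'image' uses the whole enhanced image's value for every
        block.
    """

    omega: float = 1.2
    dilate_px: int = 2
    y_global_scope: str = "block"

    def __post_init__(self) -> None:
        if self.omega < 1.0:
            raise ValueError("omega must be >= 1.0")
        if self.dilate_px < 0:
            raise ValueError("dilate_px must be >= 0")
        if self.y_global_scope not in ("block", "image"):
            raise ValueError("y_global_scope must be 'block' or 'image'")


@dataclass(frozen=True)
class BlockGrid:
    """k×k tiling of an H×W image into half-open, 0-based rectangles."""

    k: int
    bounds: tuple[tuple[int, int, int, int], ...]  # (row_start, row_end, col_start, col_end)


def make_grid(height: int, width: int, k: int) -> BlockGrid:
    """Tile an image into k² near-equal blocks (side lengths differ ≤ 1 px)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(height, width) / 8:
        raise ValueError(f"k={k} too large for a {height}x{width} image (need k <= min/8)")
    r_edges = [i * height // k for i in range(k + 1)]
    c_edges = [j * width // k for j in range(k + 1)]
    bounds = tuple(
        (r_edges[i], r_edges[i + 1], c_edges[j], c_edges[j + 1])
        for i in range(k)
        for j in range(k)
    )
    return BlockGrid(k=k, bounds=bounds)


def detect_local(
    block: np.ndarray,
    params: LocalParams | None = None,
    y_global_override: float | None = None,
) -> np.ndarray:
    """Flag pixels of the enhanced block with y ≥ ω·Y_global, then dilate.

    ``y_global_override`` substitutes a whole-image chromatic luminance for
    the per-block one.  An all-black block yields an empty mask.
    """
    block = validate_rgb(block)
    params = params or LocalParams()
    enhanced = chroma_enhance(block)
    try:
        lum = luminance_fields(enhanced)
    except DegenerateInputError:
        return np.zeros(block.shape[:2], bool)
    y_global = lum.y_global if y_global_override is None else y_global_override
    mask = lum.y_pixel >= params.omega * y_global
    if params.dilate_px and mask.any():
        mask = ndimage.binary_dilation(mask, _STRUCT8, iterations=params.dilate_px)
    return mask


def run_local_stage(
    img: np.ndarray,
    k: int = 3,
    params: LocalParams | None = None,
    patch_size: int = 9,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect and repair every block; returns (image, union of block masks).

    Clean blocks are copied bit-exact.  A block that cannot be repaired —
    its mask covers the whole block, or no fully-known source patch exists —
    is left unchanged (with a warning); the integration stage then relies on
    the global repair for that region.
    """
    img = validate_rgb(img)
    params = params or LocalParams()
    grid = make_grid(img.shape[0], img.shape[1], k)
    out = img.copy()
    union = np.zeros(img.shape[:2], bool)

    override = None
    if params.y_global_scope == "image":
        try:
            override = luminance_fields(chroma_enhance(img)).y_global
        except DegenerateInputError:
            return out, union

    for r0, r1, c0, c1 in grid.bounds:
        block = img[r0:r1, c0:c1]
        mask = detect_local(block, params, y_global_override=override)
        if not mask.any():
            continue
        union[r0:r1, c0:c1] = mask
        if mask.all():
            logger.warning(
                "block (%d:%d, %d:%d) fully masked; leaving it to the global repair",
                r0, r1, c0, c1,
            )
            continue
        try:
            out[r0:r1, c0:c1] = inpaint(block, mask, patch_size)
        except NoSourceError:
            logger.warning(
                "block (%d:%d, %d:%d): no fully-known source patch; "
                "leaving it to the global repair",
                r0, r1, c0, c1,
            )
    return out, union
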