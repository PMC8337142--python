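"""Reading and writing images and SR masks.

Color images are 8-bit RGB PNG/JPEG; masks are single-channel PNG with
0 = non-SR and 255 = SR.  Anything else (palettes, alpha, 16-bit) is
normalized to these conventions on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .color import validate_mask, validate_rgb

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as an H×W×3 uint8 RGB array."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    return validate_rgb(arr)


def write_image(path: str | Path, img: np.ndarray) -> None:
    img = validate_rgb(img)
    Image.fromarray(img, mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask PNG; any nonzero pixel counts as SR."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask {path!r}: {exc}") from exc
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = validate_mask(mask)
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)
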