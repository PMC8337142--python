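"""Orchestration of the three stages, plus the parameter-sweep experiments.

The full pipeline resizes the input to the working size, runs the global
(smooth) and local (texture-preserving) repairs independently on the
original pixels, and merges them with the per-pixel HSV maximum.  The sweep
helpers reproduce the two standard parameter studies — number of blocks
k² ∈ {1, 4, 9, 16, 25} and local coefficient ω ∈ {1.0, 1.1, 1.2, 1.3} —
and, when a phantom with ground truth is supplied, attach quantitative
detection/restoration scores to every row.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .color import MIN_SIDE, validate_rgb
from .config import PipelineConfig
from .global_stage import run_global_stage
from .integrate import integrate
from .io import read_image, write_image, write_mask
from .local_stage import LocalParams, detect_local, make_grid, run_local_stage
from .phantom import Phantom, score_detection, score_restoration

__all__ = [
    "PipelineResult",
    "resize_image",
    "run_arrays",
    "run_pipeline",
    "sweep_blocks",
    "sweep_omega",
    "BLOCK_SWEEP_KS",
    "OMEGA_SWEEP",
]

logger = logging.getLogger(__name__)

#: Grid sides of the block-count study (k² = 1, 4, 9, 16, 25 blocks).
BLOCK_SWEEP_KS = (1, 2, 3, 4, 5)
#: Coefficients of the local-detection study.
OMEGA_SWEEP = (1.0, 1.1, 1.2, 1.3)


@dataclass(frozen=True)
class PipelineResult:
    final: np.ndarray
    global_img: np.ndarray
    global_mask: np.ndarray
    local_img: np.ndarray
    local_mask: np.ndarray

    @property
    def union_mask(self) -> np.ndarray:
        return self.global_mask | self.local_mask


def resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to size×size (no-op when already that shape)."""
    img = validate_rgb(img, min_side=MIN_SIDE)
    if img.shape[:2] == (size, size):
        return img.copy()
    out = _sk_resize(img, (size, size), order=1, anti_aliasing=False, preserve_range=True)
    return np.rint(out).astype(np.uint8)


def run_arrays(img: np.ndarray, config: PipelineConfig | None = None) -> PipelineResult:
    """Run all three stages on an in-memory image (already working-sized)."""
    img = validate_rgb(img, min_side=MIN_SIDE)
    config = config or PipelineConfig()

    t0 = time.perf_counter()
    global_img, global_mask = run_global_stage(img, config.global_params)
    logger.info(
        "global stage: %.3fs, %d mask pixels",
        time.perf_counter() - t0, int(global_mask.sum()),
    )

    t0 = time.perf_counter()
    local_img, local_mask = run_local_stage(
        img, config.k, config.local_params, config.patch_size
    )
    logger.info(
        "local stage (k=%d): %.3fs, %d mask pixels",
        config.k, time.perf_counter() - t0, int(local_mask.sum()),
    )

    t0 = time.perf_counter()
    final = integrate(global_img, local_img, config.hue_mode).image
    logger.info("integration: %.3fs", time.perf_counter() - t0)

    return PipelineResult(
        final=final,
        global_img=global_img,
        global_mask=global_mask,
        local_img=local_img,
        local_mask=local_mask,
    )


def run_pipeline(
    input_path: str | Path,
    config: PipelineConfig | None = None,
    output_path: str | Path | None = None,
) -> dict[str, Path]:
    """Read, resize, repair and write; returns the paths written.

    With ``config.save_intermediates`` the global/local images and masks are
    written next to the final output (5 files in total).
    """
    config = config or PipelineConfig()
    input_path = Path(input_path)
    img = resize_image(read_image(input_path), config.resize)
    result = run_arrays(img, config)

    if output_path is None:
        output_path = input_path.with_name(input_path.stem + "_despeckled.png")
    output_path = Path(output_path)
    write_image(output_path, result.final)
    paths = {"final": output_path}
    if config.save_intermediates:
        stem = output_path.with_suffix("")
        targets = {
            "global_img": (f"{stem}_global.png", result.global_img, write_image),
            "local_img": (f"{stem}_local.png", result.local_img, write_image),
            "global_mask": (f"{stem}_global_mask.png", result.global_mask, write_mask),
            "local_mask": (f"{stem}_local_mask.png", result.local_mask, write_mask),
        }
        for name, (p, arr, writer) in targets.items():
            writer(p, arr)
            paths[name] = Path(p)
    return paths


def _scored_row(
    row: dict, result: PipelineResult, phantom: Phantom | None
) -> dict:
    row["mask_area"] = int(result.union_mask.sum())
    if phantom is not None:
        precision, recall, iou = score_detection(result.union_mask, phantom.truth_mask)
        psnr, mae = score_restoration(result.final, phantom.clean, phantom.truth_mask)
        row.update(
            precision=precision, recall=recall, iou=iou, psnr=psnr, mae=mae
        )
    return row


def sweep_blocks(
    img: np.ndarray, config: PipelineConfig | None = None, phantom: Phantom | None = None
) -> list[dict]:
    """Run the pipeline at k = 1..5; one report row per block count.

    Rows carry k, the block count k², the detected mask area and wall time;
    with a phantom also precision/recall/IoU of the union mask and PSNR/MAE
    of the final image over the truth mask.
    """
    config = config or PipelineConfig()
    rows = []
    for k in BLOCK_SWEEP_KS:
        t0 = time.perf_counter()
        result = run_arrays(img, replace(config, k=k))
        row = {"k": k, "blocks": k * k, "seconds": time.perf_counter() - t0}
        rows.append(_scored_row(row, result, phantom))
    return rows


def sweep_omega(
    img: np.ndarray, config: PipelineConfig | None = None, phantom: Phantom | None = None
) -> list[dict]:
    """Local detection at ω ∈ {1.0, 1.1, 1.2, 1.3}; one row per coefficient.

    Reports the detected local mask area (union over the k×k blocks, without
    dilation so the raw threshold behaviour is visible) and, with a phantom,
    detection scores of that mask.  The area is non-increasing in ω.
    """
    config = config or PipelineConfig()
    img = validate_rgb(img, min_side=MIN_SIDE)
    grid = make_grid(img.shape[0], img.shape[1], config.k)
    rows = []
    for omega in OMEGA_SWEEP:
        params = LocalParams(
            omega=omega, dilate_px=0, y_global_scope=config.local_params.y_global_scope
        )
        mask = np.zeros(img.shape[:2], bool)
        for r0, r1, c0, c1 in grid.bounds:
            mask[r0:r1, c0:c1] = detect_local(img[r0:r1, c0:c1], params)
        row: dict = {"omega": omega, "mask_area": int(mask.sum())}
        if phantom is not None:
            precision, recall, iou = score_detection(mask, phantom.truth_mask)
            row.update(precision=precision, recall=recall, iou=iou)
        rows.append(row)
    return rows
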