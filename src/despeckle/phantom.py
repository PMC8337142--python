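"""Synthetic cervix-like phantoms with known specular ground truth.

Clinical colposcopy frames have no highlight-free reference, so quantitative
evaluation runs on phantoms: a smooth pinkish tissue field with darker
vessel-like strokes, small elliptical specular (SR) spots pushed toward
white (high V, near-zero S) whose support is the ground-truth mask, and
larger, dimmer acetowhite-like (AW) patches that act as false-positive
confounders and are *not* part of the truth mask.  The corrupted image
equals the clean image everywhere outside the truth mask, so restoration
error can be measured exactly where damage was planted.

All randomness flows through the single seed in :class:`PhantomSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import line

from .color import DegenerateInputError, hsv_to_rgb, validate_mask, validate_rgb

__all__ = [
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "score_detection",
    "score_restoration",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; ``seed`` is the only source of randomness.

    Spot parameters emulate specular glare (tiny, V ≥ ``spot_v_floor``,
    S ≤ ``spot_sat``); AW parameters emulate acetowhite epithelium (much
    larger, V in ``aw_v``, moderately saturated so it reads as pale pink).
    """

    seed: int
    size: int = 224
    n_spots: int = 5
    spot_radius: tuple[float, float] = (2.0, 5.0)
    spot_v_floor: float = 0.98
    spot_sat: float = 0.03
    n_aw: int = 2
    aw_radius: tuple[float, float] = (12.0, 20.0)
    aw_v: tuple[float, float] = (0.78, 0.88)
    aw_sat: tuple[float, float] = (0.25, 0.35)
    n_vessels: int = 8

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.n_spots < 0 or self.n_aw < 0 or self.n_vessels < 0:
            raise ValueError("counts must be nonnegative")
        if not (0.9 <= self.spot_v_floor <= 1.0):
            raise ValueError("spot_v_floor must lie in [0.9, 1]")


@dataclass(frozen=True)
class Phantom:
    clean: np.ndarray       # reference image without specular damage
    corrupted: np.ndarray   # clean + planted SR spots
    truth_mask: np.ndarray  # bool support of the planted spots
    aw_mask: np.ndarray     # bool support of the acetowhite confounders
    spec: PhantomSpec


def _pink_hsv(h: float, s: float, v: float) -> np.ndarray:
    return hsv_to_rgb(np.array([[[h, s, v]]])).reshape(3).astype(np.float64)


def _ellipse_rho2(size: int, center: tuple[float, float], radii: tuple[float, float]) -> np.ndarray:
    """Squared normalized radius of every pixel from an axis-aligned ellipse."""
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically render (clean, corrupted, truth mask) for *spec*.

    Spots whose ellipse crosses the border are clipped by the image bounds;
    a spec with zero spots yields corrupted == clean and an empty mask.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size

    # -- smooth pink tissue field: low-frequency noise between two pink tones
    field = ndimage.gaussian_filter(rng.normal(size=(n, n)), sigma=n / 9.0, mode="reflect")
    lo, hi = field.min(), field.max()
    t = (field - lo) / (hi - lo) if hi > lo else np.zeros_like(field)
    dark = np.array([196.0, 118.0, 132.0])
    light = np.array([236.0, 162.0, 172.0])
    img = dark + t[..., None] * (light - dark)

    # -- darker curvilinear vessel strokes (random walks, slightly blurred in)
    vessel = np.zeros((n, n), np.float64)
    for _ in range(spec.n_vessels):
        r, c = rng.uniform(5, n - 5, 2)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(rng.integers(6, 14)):
            ang += rng.normal(0.0, 0.5)
            step = rng.uniform(6, 16)
            r2 = float(np.clip(r + step * np.sin(ang), 0, n - 1))
            c2 = float(np.clip(c + step * np.cos(ang), 0, n - 1))
            rr, cc = line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
            vessel[rr, cc] = 1.0
            r, c = r2, c2
    vessel = np.clip(ndimage.gaussian_filter(vessel, 0.9) * 1.8, 0.0, 1.0)
    vessel_color = np.array([150.0, 62.0, 84.0])
    img = img * (1.0 - 0.6 * vessel[..., None]) + vessel_color * 0.6 * vessel[..., None]

    # -- acetowhite-like patches: large, soft-edged, dimmer than glare,
    #    moderately saturated; part of the anatomy, hence of the clean image
    aw_mask = np.zeros((n, n), bool)
    for _ in range(spec.n_aw):
        rad = rng.uniform(*spec.aw_radius, size=2)
        margin = rad.max() + 2
        center = rng.uniform(margin, n - margin, 2)
        rho2 = _ellipse_rho2(n, (center[0], center[1]), (rad[0], rad[1]))
        w = np.exp(-2.0 * rho2)
        w[rho2 > 1.0] = 0.0
        color = _pink_hsv(0.96, rng.uniform(*spec.aw_sat), rng.uniform(*spec.aw_v))
        img = img * (1.0 - w[..., None]) + color * w[..., None]
        aw_mask |= rho2 <= 1.0

    clean = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # -- specular spots: small ellipses clamped to near-white inside their
    #    support; the support is the ground truth
    corrupted = clean.copy()
    truth = np.zeros((n, n), bool)
    aw_clearance = ndimage.binary_dilation(aw_mask, iterations=3) if aw_mask.any() else aw_mask
    for _ in range(spec.n_spots):
        # keep spots off the AW confounders (3 px clearance): the ground
        # truth must stay disjoint from the patches whose suppression the
        # phantom exists to measure
        support = None
        for _attempt in range(64):
            rad = rng.uniform(*spec.spot_radius, size=2)
            center = rng.uniform(2.0, n - 2.0, 2)
            rho2 = _ellipse_rho2(n, (center[0], center[1]), (rad[0], rad[1]))
            cand = rho2 <= 1.0
            if cand.any() and not (cand & aw_clearance).any():
                support = cand
                break
        if support is None:
            continue
        v = spec.spot_v_floor + (1.0 - spec.spot_v_floor) * (1.0 - rho2[support])
        s = spec.spot_sat
        pix = np.stack([v, v * (1.0 - 0.6 * s), v * (1.0 - s)], axis=-1) * 255.0
        corrupted[support] = np.clip(np.rint(pix), 0, 255).astype(np.uint8)
        truth |= support

    return Phantom(
        clean=clean, corrupted=corrupted, truth_mask=truth, aw_mask=aw_mask, spec=spec
    )


def default_phantom(seed: int, **overrides) -> Phantom:
    """The standard evaluation phantom (224×224, 5 spots, 2 AW patches)."""
    return generate_phantom(replace(PhantomSpec(seed=seed), **overrides))


def score_detection(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(precision, recall, IoU) of a predicted mask against ground truth.

    Empty prediction/truth follow the usual conventions: an empty side
    scores 1.0 on its own ratio, and two empty masks agree perfectly.
    """
    pred = validate_mask(pred)
    truth = validate_mask(truth, pred.shape)
    tp = float(np.count_nonzero(pred & truth))
    p = float(np.count_nonzero(pred))
    t = float(np.count_nonzero(truth))
    u = float(np.count_nonzero(pred | truth))
    precision = 1.0 if p == 0 else tp / p
    recall = 1.0 if t == 0 else tp / t
    iou = 1.0 if u == 0 else tp / u
    return precision, recall, iou


def score_restoration(
    output: np.ndarray, clean: np.ndarray, region: np.ndarray
) -> tuple[float, float]:
    """(PSNR dB, mean absolute error) over the region's pixels only.

    A perfect restoration has MSE 0; its PSNR is reported as ``inf``.
    Raises :class:`DegenerateInputError` on an empty region.
    """
    output = validate_rgb(output)
    clean = validate_rgb(clean)
    region = validate_mask(region, output.shape[:2])
    if clean.shape != output.shape:
        raise ValueError("image shapes differ")
    if not region.any():
        raise DegenerateInputError("restoration score undefined on an empty region")
    diff = output[region].astype(np.float64) - clean[region].astype(np.float64)
    mae = float(np.abs(diff).mean())
    mse = float((diff**2).mean())
    psnr = float("inf") if mse == 0.0 else 10.0 * np.log10(255.0**2 / mse)
    return psnr, mae
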