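"""Exemplar-based (Criminisi-style) inpainting of specular regions.

The hole Ω is filled patch-by-patch from its boundary ∂Ω inward.  Each
iteration picks the boundary pixel p maximizing the priority

    P(p) = C(p) · D(p)

where the *confidence term* C(p) measures how much already-known information
surrounds p (mean confidence over the known part of the patch Ψ_p) and the
*data term* D(p) = |∇I⊥_p · n_p| / α measures how strongly an isophote
(level line of intensity) flows into the front at p — so linear structures
are propagated before flat texture.  The best-matching source patch is the
fully-known window minimizing the sum of squared RGB differences (SSD) over
the known pixels of Ψ_p; its pixels are copied into the unknown part of Ψ_p,
whose confidence is set to C(p).  The loop repeats until Ω is empty.

Everything is deterministic: boundary pixels are enumerated in row-major
order, priority and SSD ties are broken by scan order, SSD is computed in
exact integer arithmetic, and there is no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.util import view_as_windows

from .color import validate_mask, validate_rgb

__all__ = [
    "FillState",
    "NoSourceError",
    "UnrepairableMaskError",
    "fill_front",
    "confidence_term",
    "data_term",
    "priority",
    "best_match",
    "fill_and_update",
    "inpaint",
]

#: Normalization factor α of the data term for 8-bit images.
ALPHA = 255.0

#: Gaussian width (pixels) used to smooth the binary hole mask before taking
#: its gradient as the fill-front normal.
NORMAL_SIGMA = 1.0

_LUMA = (0.299, 0.587, 0.114)  # ITU-R BT.601 grayscale weights


class UnrepairableMaskError(ValueError):
    """The mask leaves no known pixels to repair from."""


class NoSourceError(RuntimeError):
    """No fully-known candidate patch exists in the search region."""


@dataclass
class FillState:
    """Mutable state of one inpainting run.

    ``known`` is the complement of the hole: True on Φ (and on pixels filled
    so far), False on the remaining Ω.  ``confidence`` starts at 1 on Φ and
    0 on Ω, and never exceeds 1.
    """

    image: np.ndarray
    known: np.ndarray
    confidence: np.ndarray
    patch_size: int = 9

    half: int = field(init=False)

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be an odd integer >= 3")
        self.half = self.patch_size // 2

    @classmethod
    def from_mask(cls, image: np.ndarray, mask: np.ndarray, patch_size: int = 9) -> "FillState":
        image = validate_rgb(image)
        mask = validate_mask(mask, image.shape[:2])
        if mask.all():
            raise UnrepairableMaskError("mask covers the whole image")
        known = ~mask
        return cls(
            image=image.copy(),
            known=known,
            confidence=known.astype(np.float64),
            patch_size=patch_size,
        )

    def patch_bounds(self, p: tuple[int, int]) -> tuple[int, int, int, int]:
        """Half-open bounds of Ψ_p clipped to the image."""
        r, c = p
        h, w = self.known.shape
        return (
            max(r - self.half, 0),
            min(r + self.half + 1, h),
            max(c - self.half, 0),
            min(c + self.half + 1, w),
        )


def fill_front(state: FillState) -> list[tuple[int, int]]:
    """Pixels of Ω with at least one 4-neighbor in Φ, in row-major order.

    Empty when Ω is empty — the loop's termination condition.
    """
    known = state.known
    hole = ~known
    neigh = np.zeros_like(known)
    neigh[1:, :] |= known[:-1, :]
    neigh[:-1, :] |= known[1:, :]
    neigh[:, 1:] |= known[:, :-1]
    neigh[:, :-1] |= known[:, 1:]
    rr, cc = np.nonzero(hole & neigh)
    return list(zip(rr.tolist(), cc.tolist()))


def confidence_term(state: FillState, p: tuple[int, int]) -> float:
    """C(p): mean confidence over Ψ_p, counting unknown pixels as zero.

    The denominator is the area of the *clipped* patch, so border pixels are
    not penalized for the part of Ψ_p lying outside the image.
    """
    r0, r1, c0, c1 = state.patch_bounds(p)
    conf = state.confidence[r0:r1, c0:c1]
    known = state.known[r0:r1, c0:c1]
    return float(conf[known].sum()) / ((r1 - r0) * (c1 - c0))


def _gray(state: FillState) -> np.ndarray:
    f = state.image.astype(np.float64)
    return _LUMA[0] * f[..., 0] + _LUMA[1] * f[..., 1] + _LUMA[2] * f[..., 2]


def _known_gradient(gray: np.ndarray, known: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Gradient of the grayscale image at (r, c) from known pixels only.

    Central difference when both straddling neighbors are known; otherwise a
    one-sided difference over the nearest known pair on either side (the pair
    below/left is preferred, for determinism); otherwise 0.  The center pixel
    itself is on the fill front, hence unknown and never used.
    """
    h, w = gray.shape

    def k(rr: int, cc: int) -> bool:
        return 0 <= rr < h and 0 <= cc < w and bool(known[rr, cc])

    def axis(d: tuple[int, int]) -> float:
        dr, dc = d
        if k(r - dr, c - dc) and k(r + dr, c + dc):
            return (gray[r + dr, c + dc] - gray[r - dr, c - dc]) / 2.0
        if k(r - dr, c - dc) and k(r - 2 * dr, c - 2 * dc):
            return gray[r - dr, c - dc] - gray[r - 2 * dr, c - 2 * dc]
        if k(r + dr, c + dc) and k(r + 2 * dr, c + 2 * dc):
            return gray[r + 2 * dr, c + 2 * dc] - gray[r + dr, c + dc]
        return 0.0

    return axis((1, 0)), axis((0, 1))  # (d/drow, d/dcol)


def _front_normals(known: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradient fields of the Gaussian-smoothed hole mask (unnormalized)."""
    smooth = ndimage.gaussian_filter((~known).astype(np.float64), NORMAL_SIGMA)
    gr = np.zeros_like(smooth)
    gc = np.zeros_like(smooth)
    gr[1:-1, :] = (smooth[2:, :] - smooth[:-2, :]) / 2.0
    gr[0, :] = smooth[1, :] - smooth[0, :]
    gr[-1, :] = smooth[-1, :] - smooth[-2, :]
    gc[:, 1:-1] = (smooth[:, 2:] - smooth[:, :-2]) / 2.0
    gc[:, 0] = smooth[:, 1] - smooth[:, 0]
    gc[:, -1] = smooth[:, -1] - smooth[:, -2]
    return gr, gc


def _data_term_at(
    gray: np.ndarray,
    known: np.ndarray,
    normals: tuple[np.ndarray, np.ndarray],
    p: tuple[int, int],
) -> float:
    r, c = p
    dgr, dgc = _known_gradient(gray, known, r, c)
    nr, nc = normals[0][r, c], normals[1][r, c]
    norm = float(np.hypot(nr, nc))
    if norm == 0.0:
        return 0.0
    # isophote = rotate (dgr, dgc) by 90 degrees -> (-dgc, dgr)
    return abs(-dgc * (nr / norm) + dgr * (nc / norm)) / ALPHA


def data_term(state: FillState, p: tuple[int, int]) -> float:
    """D(p) = |∇I⊥_p · n_p| / α.

    The isophote direction is the 90°-rotated image gradient estimated from
    known pixels near p; the front normal is the normalized gradient of the
    σ=1 smoothed hole mask.  Either vector degenerate (no usable gradient,
    flat mask) gives D = 0.
    """
    return _data_term_at(_gray(state), state.known, _front_normals(state.known), p)


def priority(state: FillState, p: tuple[int, int]) -> float:
    """P(p) = C(p) · D(p)."""
    return confidence_term(state, p) * data_term(state, p)


def _candidate_ssd(state: FillState, target: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Integer SSD of every full-size window against the target's known pixels.

    Returns (ssd, valid): ssd is (nH, nW) int64 over window top-left corners,
    valid marks windows fully contained in the known region.
    """
    ps = state.patch_size
    r, c = target
    r0, r1, c0, c1 = state.patch_bounds(target)
    tk = state.known[r0:r1, c0:c1]
    trr, tcc = np.nonzero(tk)  # row-major offsets of known target cells
    tvals = state.image[r0 + trr, c0 + tcc].astype(np.int64)

    img_wins = view_as_windows(state.image, (ps, ps, 3))[:, :, 0]
    known_wins = view_as_windows(state.known, (ps, ps))
    valid = known_wins.all(axis=(2, 3))

    # offsets of the target's known cells relative to the patch center,
    # mapped into full-window coordinates
    wr = trr + (r0 - (r - state.half))
    wc = tcc + (c0 - (c - state.half))
    diffs = img_wins[:, :, wr, wc, :].astype(np.int64) - tvals
    ssd = np.einsum("ijkl,ijkl->ij", diffs, diffs)
    return ssd, valid


def best_match(state: FillState, target: tuple[int, int]) -> tuple[int, int]:
    """Center of the fully-known window minimizing SSD against Ψ_target.

    SSD is summed over the known pixels of the (clipped) target patch in
    exact int64 arithmetic; ties go to the earlier window in row-major scan
    order.  Raises :class:`NoSourceError` when no window is fully known.
    """
    ssd, valid = _candidate_ssd(state, target)
    if not valid.any():
        raise NoSourceError("no fully-known candidate patch in the search region")
    ssd = np.where(valid, ssd, np.iinfo(np.int64).max)
    flat = int(np.argmin(ssd))  # first minimum in row-major order
    qr, qc = divmod(flat, ssd.shape[1])
    return (qr + state.half, qc + state.half)


def fill_and_update(
    state: FillState,
    target: tuple[int, int],
    source: tuple[int, int],
    new_confidence: float | None = None,
) -> FillState:
    """Copy source pixels into the unknown part of Ψ_target, in place.

    Only unknown target pixels change; their confidence becomes C(target) as
    evaluated *before* the fill (pass ``new_confidence`` to reuse a value
    already computed during priority selection).
    """
    if new_confidence is None:
        new_confidence = confidence_term(state, target)
    r0, r1, c0, c1 = state.patch_bounds(target)
    sub_known = state.known[r0:r1, c0:c1]
    if sub_known.all():
        return state
    dr = source[0] - target[0]
    dc = source[1] - target[1]
    urr, ucc = np.nonzero(~sub_known)
    rr, cc = r0 + urr, c0 + ucc
    state.image[rr, cc] = state.image[rr + dr, cc + dc]
    state.confidence[rr, cc] = new_confidence
    state.known[rr, cc] = True
    return state


def inpaint(image: np.ndarray, mask: np.ndarray, patch_size: int = 9) -> np.ndarray:
    """Remove the masked region by iterative exemplar filling.

    Terminates in at most |Ω| iterations (every step fills at least the
    selected front pixel).  Pixels outside the mask are returned bit-exact.
    """
    mask = validate_mask(mask, np.asarray(image).shape[:2])
    if not mask.any():
        return validate_rgb(image).copy()
    state = FillState.from_mask(image, mask, patch_size)
    while True:
        front = fill_front(state)
        if not front:
            break
        gray = _gray(state)
        normals = _front_normals(state.known)
        best_p = None
        best_pri = -1.0
        best_conf = 0.0
        for p in front:
            conf = confidence_term(state, p)
            pri = conf * _data_term_at(gray, state.known, normals, p)
            if pri > best_pri:
                best_p, best_pri, best_conf = p, pri, conf
        source = best_match(state, best_p)
        fill_and_update(state, best_p, source, new_confidence=best_conf)
    return state.image
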