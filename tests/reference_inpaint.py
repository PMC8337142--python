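"""Naive reference implementation of exemplar inpainting, for test oracles.

Deliberately written with plain Python loops and scalar arithmetic, mirroring
the textbook priority/SSD rules directly so it stays independent of the
vectorized engine in :mod:`despeckle.exemplar`.  Shared deterministic
conventions (which both implementations must follow for outputs to be
comparable bit-for-bit): row-major enumeration everywhere, strict-`>`/`<`
comparisons so ties go to the earliest candidate, integer SSD, fill-front
normal from the σ=1 Gaussian-smoothed hole mask, and grayscale gradients
from known pixels only (central difference, else the nearest known pair on
either side, else zero).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

LUMA = (0.299, 0.587, 0.114)


def _gray(image):
    h, w, _ = image.shape
    g = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            px = image[r, c]
            g[r, c] = LUMA[0] * float(px[0]) + LUMA[1] * float(px[1]) + LUMA[2] * float(px[2])
    return g


def _front(known):
    h, w = known.shape
    out = []
    for r in range(h):
        for c in range(w):
            if known[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and known[rr, cc]:
                    out.append((r, c))
                    break
    return out


def _confidence(conf, known, r, c, half):
    h, w = known.shape
    r0, r1 = max(r - half, 0), min(r + half + 1, h)
    c0, c1 = max(c - half, 0), min(c + half + 1, w)
    total = 0.0
    for rr in range(r0, r1):
        for cc in range(c0, c1):
            if known[rr, cc]:
                total += conf[rr, cc]
    return total / ((r1 - r0) * (c1 - c0))


def _axis_diff(gray, known, r, c, dr, dc):
    h, w = known.shape

    def k(rr, cc):
        return 0 <= rr < h and 0 <= cc < w and known[rr, cc]

    if k(r - dr, c - dc) and k(r + dr, c + dc):
        return (gray[r + dr, c + dc] - gray[r - dr, c - dc]) / 2.0
    if k(r - dr, c - dc) and k(r - 2 * dr, c - 2 * dc):
        return gray[r - dr, c - dc] - gray[r - 2 * dr, c - 2 * dc]
    if k(r + dr, c + dc) and k(r + 2 * dr, c + 2 * dc):
        return gray[r + 2 * dr, c + 2 * dc] - gray[r + dr, c + dc]
    return 0.0


def _central(field, r, c, axis):
    h, w = field.shape
    if axis == 0:
        if 0 < r < h - 1:
            return (field[r + 1, c] - field[r - 1, c]) / 2.0
        return field[min(r + 1, h - 1), c] - field[max(r - 1, 0), c]
    if 0 < c < w - 1:
        return (field[r, c + 1] - field[r, c - 1]) / 2.0
    return field[r, min(c + 1, w - 1)] - field[r, max(c - 1, 0)]


def _data(gray, known, smooth_mask, r, c):
    nr = _central(smooth_mask, r, c, 0)
    nc = _central(smooth_mask, r, c, 1)
    norm = float(np.hypot(nr, nc))
    if norm == 0.0:
        return 0.0
    dgr = _axis_diff(gray, known, r, c, 1, 0)
    dgc = _axis_diff(gray, known, r, c, 0, 1)
    return abs(-dgc * (nr / norm) + dgr * (nc / norm)) / 255.0


def _best_source(image, known, r, c, half):
    """Full-size fully-known window with least integer SSD vs known target pixels."""
    h, w, _ = image.shape
    ps = 2 * half + 1
    r0, r1 = max(r - half, 0), min(r + half + 1, h)
    c0, c1 = max(c - half, 0), min(c + half + 1, w)
    best = None
    best_ssd = None
    for qr in range(half, h - half):
        for qc in range(half, w - half):
            ok = True
            for rr in range(qr - half, qr + half + 1):
                for cc in range(qc - half, qc + half + 1):
                    if not known[rr, cc]:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            ssd = 0
            for rr in range(r0, r1):
                for cc in range(c0, c1):
                    if not known[rr, cc]:
                        continue
                    srr = qr + (rr - r)
                    scc = qc + (cc - c)
                    for ch in range(3):
                        diff = int(image[rr, cc, ch]) - int(image[srr, scc, ch])
                        ssd += diff * diff
            if best_ssd is None or ssd < best_ssd:
                best_ssd = ssd
                best = (qr, qc)
    return best


def reference_inpaint(image, mask, patch_size=3):
    """Literal priority-driven exemplar fill; returns the repaired image."""
    image = np.array(image, dtype=np.uint8, copy=True)
    known = ~np.array(mask, dtype=bool)
    conf = known.astype(np.float64)
    half = patch_size // 2
    h, w, _ = image.shape

    while True:
        front = _front(known)
        if not front:
            return image
        gray = _gray(image)
        smooth_mask = ndimage.gaussian_filter((~known).astype(np.float64), 1.0)
        best_p = None
        best_pri = -1.0
        best_conf = 0.0
        for (r, c) in front:
            cp = _confidence(conf, known, r, c, half)
            pri = cp * _data(gray, known, smooth_mask, r, c)
            if pri > best_pri:
                best_p, best_pri, best_conf = (r, c), pri, cp
        r, c = best_p
        src = _best_source(image, known, r, c, half)
        if src is None:
            raise RuntimeError("no fully-known source patch")
        qr, qc = src
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        for rr in range(r0, r1):
            for cc in range(c0, c1):
                if known[rr, cc]:
                    continue
                image[rr, cc] = image[qr + (rr - r), qc + (cc - c)]
                conf[rr, cc] = best_conf
                known[rr, cc] = True
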