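"""Exemplar engine: front tracking, priority terms, matching, full fills."""

import numpy as np
import pytest

from despeckle import FillState, NoSourceError, UnrepairableMaskError, inpaint
from despeckle.exemplar import (
    best_match,
    confidence_term,
    data_term,
    fill_and_update,
    fill_front,
    priority,
)
from reference_inpaint import reference_inpaint


def _uniform(h, w, value=100):
    return np.full((h, w, 3), value, np.uint8)


def _state(img, mask, patch_size=3):
    return FillState.from_mask(img, np.asarray(mask, bool), patch_size)


class TestFillFront:
    def test_empty_hole(self):
        state = _state(_uniform(6, 6), np.zeros((6, 6), bool))
        assert fill_front(state) == []

    def test_single_pixel(self):
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = True
        assert fill_front(_state(_uniform(6, 6), mask)) == [(2, 3)]

    def test_square_perimeter_only(self):
        mask = np.zeros((9, 9), bool)
        mask[3:6, 3:6] = True
        front = fill_front(_state(_uniform(9, 9), mask))
        expected = [(r, c) for r in range(3, 6) for c in range(3, 6) if (r, c) != (4, 4)]
        assert front == expected  # row-major, center excluded


class TestConfidence:
    def test_fully_known_patch(self):
        mask = np.zeros((9, 9), bool)
        mask[0, 0] = True  # keep Ω nonempty, far from the probe
        state = _state(_uniform(9, 9), mask)
        assert confidence_term(state, (5, 5)) == 1.0

    def test_patch_inside_hole_at_init(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        state = _state(_uniform(9, 9), mask)
        assert confidence_term(state, (4, 4)) == 0.0

    def test_six_of_nine_known(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 3:6] = True  # hides 3 of the 9 patch cells
        state = _state(_uniform(9, 9), mask)
        assert confidence_term(state, (4, 4)) == pytest.approx(6 / 9)

    def test_clipped_patch_area_denominator(self):
        mask = np.zeros((9, 9), bool)
        mask[0, 0] = True  # corner patch clips to 2x2; 3 of 4 cells known
        state = _state(_uniform(9, 9), mask)
        assert confidence_term(state, (0, 0)) == pytest.approx(3 / 4)


class TestDataTerm:
    def test_uniform_region_is_zero(self):
        mask = np.zeros((9, 9), bool)
        mask[4:, 4:] = True
        state = _state(_uniform(9, 9), mask)
        for p in fill_front(state):
            assert data_term(state, p) == 0.0

    def test_structure_parallel_to_front_is_zero(self):
        """Horizontal isophotes meeting a horizontal front: nothing to propagate."""
        img = np.repeat((np.arange(9, dtype=np.uint8) * 20)[:, None, None], 9, 1)
        img = np.repeat(img, 3, 2)  # per-row ramp, constant along columns
        mask = np.zeros((9, 9), bool)
        mask[5:, :] = True
        state = _state(img, mask)
        assert data_term(state, (5, 4)) == 0.0

    def test_corner_gradient_hand_traced(self):
        """Quarter-plane hole, per-row ramp: D = dgr·n̂c / 255 with n̂c = 1/√2.

        At the corner (4, 4) of the hole {r ≥ 4, c ≥ 4}, the smoothed-mask
        gradient has equal row/column components by the hole's diagonal
        symmetry, so the unit normal is (1/√2, 1/√2).  The ramp's row
        derivative from the known pair above is exactly the ramp step; the
        column derivative vanishes.
        """
        step = 10
        gray_vals = (np.arange(9) * step).astype(np.uint8)
        img = np.repeat(np.repeat(gray_vals[:, None, None], 9, 1), 3, 2)
        mask = np.zeros((9, 9), bool)
        mask[4:, 4:] = True
        state = _state(img, mask)
        # grayscale of an achromatic pixel equals its channel value
        expected = step / (255.0 * np.sqrt(2.0))
        assert data_term(state, (4, 4)) == pytest.approx(expected, rel=1e-9)


class TestPriority:
    def test_zero_confidence_kills_priority(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        state = _state(_uniform(9, 9), mask)
        assert priority(state, (4, 4)) == 0.0

    def test_product_rule(self):
        mask = np.zeros((9, 9), bool)
        mask[4:, 4:] = True
        gray_vals = (np.arange(9) * 10).astype(np.uint8)
        img = np.repeat(np.repeat(gray_vals[:, None, None], 9, 1), 3, 2)
        state = _state(img, mask)
        p = (4, 4)
        assert priority(state, p) == pytest.approx(
            confidence_term(state, p) * data_term(state, p)
        )

    def test_priorities_match_naive_reference(self):
        import reference_inpaint as ref
        from scipy import ndimage

        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        mask = np.zeros((12, 12), bool)
        mask[4:8, 5:9] = True
        state = _state(img, mask)
        gray = ref._gray(img)
        smooth = ndimage.gaussian_filter(mask.astype(np.float64), 1.0)
        for p in fill_front(state):
            expected = ref._confidence(state.confidence, state.known, *p, 1) * ref._data(
                gray, state.known, smooth, *p
            )
            assert priority(state, p) == pytest.approx(expected, rel=1e-12, abs=1e-15)


class TestBestMatch:
    def test_exact_copy_found(self):
        img = np.zeros((12, 12, 3), np.uint8)
        img[2:5, 2:5] = [[[10, 20, 30], [40, 50, 60], [70, 80, 90]],
                         [[11, 21, 31], [41, 51, 61], [71, 81, 91]],
                         [[12, 22, 32], [42, 52, 62], [72, 82, 92]]]
        img[8:11, 8:11] = img[2:5, 2:5]
        mask = np.zeros((12, 12), bool)
        mask[9, 9] = True  # hide the center of the second copy
        state = _state(img, mask)
        assert best_match(state, (9, 9)) == (3, 3)

    def test_equals_exhaustive_search(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        mask = np.zeros((12, 12), bool)
        mask[5:8, 4:7] = True
        state = _state(img, mask)
        target = fill_front(state)[0]
        got = best_match(state, target)
        # brute force over every fully-known candidate
        best_ssd, best_q = None, None
        half = 1
        for qr in range(half, 11):
            for qc in range(half, 11):
                if not state.known[qr - half:qr + half + 1, qc - half:qc + half + 1].all():
                    continue
                ssd = 0
                for dr in range(-half, half + 1):
                    for dc in range(-half, half + 1):
                        tr, tc = target[0] + dr, target[1] + dc
                        if not (0 <= tr < 12 and 0 <= tc < 12 and state.known[tr, tc]):
                            continue
                        d = img[tr, tc].astype(int) - img[qr + dr, qc + dc].astype(int)
                        ssd += int((d * d).sum())
                if best_ssd is None or ssd < best_ssd:
                    best_ssd, best_q = ssd, (qr, qc)
        assert got == best_q

    def test_tie_breaks_by_scan_order(self):
        img = _uniform(10, 10)  # every candidate has SSD 0
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        state = _state(img, mask)
        assert best_match(state, (5, 5)) == (1, 1)  # first full window center

    def test_no_source_error(self):
        img = _uniform(6, 6)
        mask = np.ones((6, 6), bool)
        mask[0, 0] = False  # known region too small for any 3x3 window
        state = _state(img, mask)
        with pytest.raises(NoSourceError):
            best_match(state, fill_front(state)[0])


class TestFillAndUpdate:
    def test_hole_shrinks_by_unknown_count(self):
        img = _uniform(9, 9)
        mask = np.zeros((9, 9), bool)
        mask[4, 3:6] = True
        state = _state(img, mask)
        before = int((~state.known).sum())
        fill_and_update(state, (4, 4), (1, 1))
        assert int((~state.known).sum()) == before - 3

    def test_confidence_frozen_at_selection_value(self):
        rng = np.random.default_rng(11)
        img = rng.integers(0, 256, (9, 9, 3)).astype(np.uint8)
        mask = np.zeros((9, 9), bool)
        mask[4, 3:6] = True
        state = _state(img, mask)
        c_sel = confidence_term(state, (4, 4))
        fill_and_update(state, (4, 4), (1, 1))
        assert np.allclose(state.confidence[4, 3:6], c_sel)

    def test_noop_when_patch_fully_known(self):
        img = _uniform(9, 9)
        mask = np.zeros((9, 9), bool)
        mask[0, 0] = True
        state = _state(img, mask)
        snap = state.image.copy()
        fill_and_update(state, (5, 5), (2, 2))
        assert np.array_equal(state.image, snap)


class TestInpaint:
    def test_empty_mask_is_identity(self):
        img = _uniform(8, 8, 42)
        assert np.array_equal(inpaint(img, np.zeros((8, 8), bool), 3), img)

    def test_single_pixel_in_uniform_image(self):
        img = _uniform(8, 8, 131)
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        out = inpaint(img, mask, 3)
        assert out[4, 4].tolist() == [131, 131, 131]

    def test_full_mask_unrepairable(self):
        with pytest.raises(UnrepairableMaskError):
            inpaint(_uniform(8, 8), np.ones((8, 8), bool), 3)

    def test_non_mask_pixels_bit_exact(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        mask = np.zeros((16, 16), bool)
        mask[5:9, 6:10] = True
        out = inpaint(img, mask, 3)
        assert np.array_equal(out[~mask], img[~mask])

    def test_two_texture_hole_matches_reference(self):
        """16×16 two-texture image, 4×4 hole: engine equals the naive rules."""
        rng = np.random.default_rng(99)
        img = np.empty((16, 16, 3), np.uint8)
        img[:, :8] = rng.integers(0, 80, (16, 8, 3))
        img[:, 8:] = rng.integers(170, 256, (16, 8, 3))
        mask = np.zeros((16, 16), bool)
        mask[6:10, 6:10] = True
        assert np.array_equal(inpaint(img, mask, 3), reference_inpaint(img, mask, 3))

    def test_confidence_stays_in_unit_interval(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        mask = np.zeros((16, 16), bool)
        mask[4:9, 4:9] = True
        state = FillState.from_mask(img, mask, 3)
        from despeckle.exemplar import _data_term_at, _front_normals, _gray

        while True:
            front = fill_front(state)
            if not front:
                break
            confs = [confidence_term(state, p) for p in front]
            best = int(np.argmax([
                c * _data_term_at(_gray(state), state.known, _front_normals(state.known), p)
                for c, p in zip(confs, front)
            ]))
            fill_and_update(state, front[best], best_match(state, front[best]),
                            new_confidence=confs[best])
            assert (state.confidence >= 0).all() and (state.confidence <= 1).all()
        assert state.known.all()
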