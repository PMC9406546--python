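"""Breast detection, pectoral exclusion and the 7-step normalization."""

import numpy as np
import pytest
from skimage import measure

from mammodense.errors import DegenerateHistogram, NoThresholdFound
from mammodense.evaluation import dice
from mammodense.phantom import PhantomSpec, generate_phantom
from mammodense.preprocessing import (BreastMask, RawMammogram, detect_breast,
                                      exclude_pectoral, normalize_histogram,
                                      orient_left, preprocess)


def _blob_image(side=96, breast_level=0.7, extra=None):
    """Background 0 with a solid left-attached rectangle 'breast'."""
    img = np.zeros((side, side))
    img[20:70, :40] = breast_level
    if extra is not None:
        img[extra] = extra[2] if len(extra) > 2 else 0.2
    return img


class TestOrientLeft:
    def test_left_breast_unchanged(self):
        img = RawMammogram(_blob_image() * 100 + 1)
        out = orient_left(img)
        assert out is img and not out.flipped

    def test_right_breast_mirrored(self):
        base = _blob_image() * 100 + 1
        img = RawMammogram(base[:, ::-1])
        out = orient_left(img)
        assert out.flipped
        np.testing.assert_array_equal(out.pixels, base)

    def test_symmetric_tie_counts_as_left(self):
        img = RawMammogram(np.ones((64, 64)) + np.eye(64)[:, ::-1] + np.eye(64))
        assert not orient_left(img).flipped

    def test_idempotent(self):
        img = RawMammogram(_blob_image()[:, ::-1] * 10 + 1)
        once = orient_left(img)
        twice = orient_left(once)
        np.testing.assert_array_equal(once.pixels, twice.pixels)


class TestDetectBreast:
    def test_two_level_image(self):
        img = RawMammogram(_blob_image())
        mask = detect_breast(img)
        np.testing.assert_array_equal(mask.mask, _blob_image() > 0)

    def test_dim_disconnected_artifact_excluded(self):
        # brute-force oracle: scan every unique value, count 8-connected
        # components of both phases, first threshold reaching exactly two
        img = _blob_image()
        img[80:88, 60:68] = 0.2          # artifact far from the breast
        raw = RawMammogram(img)
        values, counts = np.unique(img, return_counts=True)
        mode = values[np.argmax(counts)]
        expected_t = None
        for t in values[values > mode]:
            b = img >= t
            n = measure.label(b, connectivity=2).max() + \
                measure.label(~b, connectivity=2).max()
            if n == 2:
                expected_t = t
                break
        mask = detect_breast(raw)
        assert mask.breast_threshold == expected_t
        assert expected_t > 0.2          # artifact below the chosen threshold
        assert not mask.mask[80:88, 60:68].any()

    def test_constant_image_raises(self):
        with pytest.raises(NoThresholdFound):
            detect_breast(RawMammogram(np.full((64, 64), 7.0)))

    def test_monotone_relabeling_invariance(self):
        img = _blob_image()
        img[80:88, 60:68] = 0.2
        m1 = detect_breast(RawMammogram(img)).mask
        m2 = detect_breast(RawMammogram(np.exp(3 * img) + 5)).mask
        np.testing.assert_array_equal(m1, m2)


class TestExcludePectoral:
    def test_mlo_polygon_tracks_triangle_hypotenuse(self):
        spec = PhantomSpec(size=(128, 128), view="MLO", seed=5)
        raw, _, _, geom = generate_phantom(spec)
        mask = detect_breast(raw)
        poly = exclude_pectoral(raw, mask)
        assert not poly.empty
        c_top, r_bot = geom["triangle"]["c_top"], geom["triangle"]["r_bot"]
        row_step = 8     # scaled step at this resolution
        for r, c in poly.vertices[1:]:
            c_true = c_top * (1 - r / r_bot)
            assert abs(c - c_true) <= 2 * row_step

    def test_cc_view_returns_empty_polygon(self):
        spec = PhantomSpec(size=(128, 128), view="CC", seed=5)
        raw, _, _, _ = generate_phantom(spec)
        mask = detect_breast(raw)
        before = mask.mask.copy()
        poly = exclude_pectoral(raw, mask)
        assert poly.empty
        np.testing.assert_array_equal(mask.mask, before)

    def test_large_triangle_mostly_removed(self):
        spec = PhantomSpec(size=(128, 128), view="MLO", seed=3,
                           triangle_frac=(0.5, 0.5))
        raw, _, _, geom = generate_phantom(spec)
        mask = detect_breast(raw)
        before = mask.mask.copy()
        poly = exclude_pectoral(raw, mask)
        tri = np.zeros_like(before)
        rr, cc = np.mgrid[0:128, 0:128]
        tri[(cc / geom["triangle"]["c_top"] + rr / geom["triangle"]["r_bot"]) <= 1] = 1
        removed = before & ~mask.mask
        assert (removed & tri).sum() >= 0.9 * (before & tri).sum()

    def test_never_removes_outside_top_left_half(self):
        for seed in range(3):
            spec = PhantomSpec(size=(128, 128), view="MLO", seed=seed)
            raw, _, _, _ = generate_phantom(spec)
            mask = detect_breast(raw)
            before = mask.mask.copy()
            exclude_pectoral(raw, mask)
            removed = before & ~mask.mask
            assert not removed[64:, :].any()
            assert not removed[:, 64:].any()


def _oracle_seven_steps(breast_values):
    """Independent scalar implementation of the normalization steps 2-7
    applied to a (already step-1 rescaled) breast sample."""
    v = breast_values - breast_values.min()
    v = v / v.max()
    v = (v - v.mean()) / v.std()
    hist, edges = np.histogram(v, bins=256)
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    v = v - mode
    p30, p70 = np.percentile(v, [30, 70])
    out = np.empty_like(v)
    for i, x in enumerate(v):
        if x < p30:
            out[i] = -1 + (x - p30)
        elif x > p70:
            out[i] = 1 + (x - p70)
        else:
            out[i] = -1 + 2 * (x - p30) / (p70 - p30)
    return (out - out.min()) / (out.max() - out.min())


class TestNormalizeHistogram:
    def _uniform_case(self):
        rng = np.random.default_rng(99)
        side = 340
        img = np.zeros((side, side))
        mask = np.zeros((side, side), bool)
        mask[:side - 40, :] = True        # ~1e5 breast pixels
        img[mask] = rng.uniform(0.2, 0.9, size=mask.sum())
        return RawMammogram(img + 1e-9), BreastMask(mask, 0.0)

    def test_matches_scalar_oracle(self):
        raw, bm = self._uniform_case()
        norm = normalize_histogram(raw, bm)
        lo, hi = raw.pixels.min(), raw.pixels.max()
        expected = _oracle_seven_steps((raw.pixels[bm.mask] - lo) / (hi - lo))
        np.testing.assert_allclose(norm.pixels[bm.mask], expected, atol=1e-9)

    def test_step2_minimum_is_exactly_zero(self):
        raw, bm = self._uniform_case()
        _, steps = normalize_histogram(raw, bm, return_steps=True)
        assert steps[1].min() == 0.0

    def test_output_in_unit_interval_background_zero(self):
        raw, bm = self._uniform_case()
        norm = normalize_histogram(raw, bm)
        assert norm.pixels.min() >= 0.0 and norm.pixels.max() <= 1.0
        assert (norm.pixels[~bm.mask] == 0).all()

    def test_affine_input_invariance(self):
        raw, bm = self._uniform_case()
        a = normalize_histogram(raw, bm).pixels
        scaled = RawMammogram(raw.pixels * 1234.5 + 67.0)
        b = normalize_histogram(scaled, bm).pixels
        assert np.abs(a - b).max() < 1e-6

    def test_constant_breast_raises(self):
        img = np.zeros((64, 64))
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        img[mask] = 0.5
        img[0, 0] = 1.0   # image itself not constant
        with pytest.raises(DegenerateHistogram):
            normalize_histogram(RawMammogram(img), BreastMask(mask, 0.0))


def test_full_preprocess_keeps_true_breast():
    """End-to-end: >= 95% of the true breast-minus-pectoral region survives."""
    for seed, view in [(0, "CC"), (1, "MLO"), (2, "MLO")]:
        raw, true_breast, _, _ = generate_phantom(
            PhantomSpec(size=(128, 128), view=view, seed=seed))
        norm = preprocess(raw)
        kept = norm.breast_mask.mask & true_breast.mask
        assert kept.sum() >= 0.95 * true_breast.mask.sum()
        assert dice(norm.breast_mask.mask, true_breast.mask) > 0.95
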