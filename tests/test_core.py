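"""Unit and property tests for the masked-NCC engine."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from empick import (
    FftCounter,
    Micrograph,
    TemplateWithMask,
    fft_op_count,
    masked_ncc,
    mean_filter,
    micrograph_spectra,
    smooth_size,
)

from conftest import spatial_masked_ncc


def is_7_smooth(n: int) -> bool:
    for p in (2, 3, 5, 7):
        while n % p == 0:
            n //= p
    return n == 1


class TestSmoothSize:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (4096, 4096),  # 2^12 already smooth
            (4097, 4116),  # 2^2 * 3 * 7^3
            (97, 98),      # 2 * 7^2
            (1, 1),
            (4255, 4320),  # 4096 + 160 - 1 pads to 2^5 * 3^3 * 5
        ],
    )
    def test_matches_brute_force_scan(self, n, expected):
        brute = next(m for m in range(n, 2 * n + 8) if is_7_smooth(m))
        assert brute == expected
        assert smooth_size(n) == expected

    @given(st.integers(min_value=1, max_value=20000))
    @settings(max_examples=200, derandomize=True)
    def test_result_is_smallest_smooth_at_least_n(self, n):
        m = smooth_size(n)
        assert m >= n and is_7_smooth(m)
        assert not any(is_7_smooth(j) for j in range(n, m))

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            smooth_size(0)


class TestMeanFilter:
    def test_preserves_constants(self):
        img = np.full((9, 7), 3.25)
        assert np.allclose(mean_filter(img, 3), 3.25)

    def test_checkerboard_interior_is_half(self):
        img = np.indices((8, 8)).sum(axis=0) % 2.0
        out = mean_filter(img, 2)
        assert np.allclose(out[1:-1, 1:-1], 0.5)

    def test_impulse_spreads_to_inverse_window_area(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        out = mean_filter(img, 4)
        assert np.isclose(out.sum(), 1.0)
        vals = out[out > 0]
        assert len(vals) == 16 and np.allclose(vals, 1 / 16)

    def test_output_shape_matches_input(self):
        assert mean_filter(np.random.default_rng(0).normal(size=(11, 5)), 4).shape == (11, 5)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            mean_filter(np.zeros((3, 3)), 5)


class TestSpectra:
    def test_zero_micrograph_gives_zero_spectra(self):
        sp = micrograph_spectra(Micrograph(pixels=np.zeros((16, 16))), (4, 4))
        assert not np.any(sp.spectrum_I) and not np.any(sp.spectrum_I2)

    def test_dc_term_is_pixel_sum(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(20, 24))
        sp = micrograph_spectra(Micrograph(pixels=img), (5, 5), precision="double")
        assert np.isclose(sp.spectrum_I[0, 0].real, img.sum())

    def test_padded_shape_is_smooth(self):
        sp = micrograph_spectra(Micrograph(pixels=np.zeros((100, 97))), (8, 8))
        assert sp.padded_shape == (smooth_size(107), smooth_size(104))
        assert all(is_7_smooth(d) for d in sp.padded_shape)

    def test_case_study_padding(self):
        # 4096x4096 micrograph with 160x160 templates pads to 4320 = 2^5*3^3*5
        assert smooth_size(4096 + 160 - 1) == 4320

    def test_exactly_two_forward_transforms(self):
        counter = FftCounter()
        micrograph_spectra(Micrograph(pixels=np.zeros((32, 32))), (8, 8), counter)
        assert counter.forward == 2 and counter.inverse == 0

    def test_oversized_template_rejected(self):
        with pytest.raises(ValueError):
            micrograph_spectra(Micrograph(pixels=np.zeros((16, 16))), (17, 4))


def random_instance(rng, max_img=32, max_tmpl=8):
    ir = int(rng.integers(max_tmpl, max_img + 1))
    ic = int(rng.integers(max_tmpl, max_img + 1))
    tr = int(rng.integers(2, max_tmpl + 1))
    tc = int(rng.integers(2, max_tmpl + 1))
    img = rng.normal(size=(ir, ic))
    timg = rng.normal(size=(tr, tc))
    while True:
        mask = (rng.random((tr, tc)) < 0.7).astype(np.uint8)
        if mask.sum() >= 2 and np.asarray(timg[mask == 1]).var() > 0:
            return img, timg, mask


class TestMaskedNcc:
    def test_exact_copy_scores_one(self):
        rng = np.random.default_rng(2)
        timg = rng.normal(size=(6, 6))
        mask = np.ones((6, 6), np.uint8)
        img = np.zeros((24, 24))
        img[10:16, 4:10] = timg
        sp = micrograph_spectra(Micrograph(pixels=img), (6, 6), precision="double")
        res = masked_ncc(sp, TemplateWithMask(image=timg, mask=mask))
        assert res.scores[10, 4] == pytest.approx(1.0, abs=1e-4)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(3)
        img, timg, mask = random_instance(rng)
        t = TemplateWithMask(image=timg, mask=mask)
        sp1 = micrograph_spectra(Micrograph(pixels=img), t.shape, precision="double")
        sp2 = micrograph_spectra(
            Micrograph(pixels=2.5 * img + 7.0), t.shape, precision="double"
        )
        a = masked_ncc(sp1, t).scores
        b = masked_ncc(sp2, t).scores
        assert np.allclose(a, b, atol=1e-5)

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence(self, seed):
        """FFT path equals the spatial-domain brute force at every offset."""
        rng = np.random.default_rng(seed)
        img, timg, mask = random_instance(rng)
        t = TemplateWithMask(image=timg, mask=mask)
        sp = micrograph_spectra(Micrograph(pixels=img), t.shape, precision="double")
        got = masked_ncc(sp, t).scores
        want = spatial_masked_ncc(img, timg, mask)
        assert np.abs(got - want).max() < 1e-6

    def test_single_precision_agrees_at_engine_tolerance(self):
        rng = np.random.default_rng(11)
        img, timg, mask = random_instance(rng)
        t = TemplateWithMask(image=timg, mask=mask)
        sp = micrograph_spectra(Micrograph(pixels=img), t.shape, precision="single")
        got = masked_ncc(sp, t).scores
        want = spatial_masked_ncc(img, timg, mask)
        assert got.dtype == np.float32
        assert np.abs(got - want).max() < 1e-4

    @pytest.mark.parametrize("seed", range(10))
    def test_scores_bounded(self, seed):
        rng = np.random.default_rng(seed + 500)
        img, timg, mask = random_instance(rng)
        t = TemplateWithMask(image=timg, mask=mask)
        sp = micrograph_spectra(Micrograph(pixels=img), t.shape)
        s = masked_ncc(sp, t).scores
        finite = s[np.isfinite(s)]
        assert finite.min() >= -1 - 1e-4 and finite.max() <= 1 + 1e-4

    @pytest.mark.parametrize("shift", [(0, 0), (3, 5), (7, 2)])
    def test_shift_equivariance(self, shift):
        rng = np.random.default_rng(4)
        timg = rng.normal(size=(5, 5))
        mask = np.ones((5, 5), np.uint8)
        t = TemplateWithMask(image=timg, mask=mask)
        base = np.zeros((30, 30))
        r0, c0 = 4, 6
        dr, dc = shift
        img = base.copy()
        img[r0 + dr : r0 + dr + 5, c0 + dc : c0 + dc + 5] = timg
        sp = micrograph_spectra(Micrograph(pixels=img), (5, 5), precision="double")
        s = masked_ncc(sp, t).scores
        assert np.unravel_index(np.argmax(s), s.shape) == (r0 + dr, c0 + dc)

    def test_padding_neutrality(self):
        rng = np.random.default_rng(5)
        img, timg, mask = random_instance(rng)
        t = TemplateWithMask(image=timg, mask=mask)
        mic = Micrograph(pixels=img)
        sp_min = micrograph_spectra(mic, t.shape, precision="double")
        bigger = (sp_min.padded_shape[0] + 13, sp_min.padded_shape[1] + 5)
        sp_big = micrograph_spectra(mic, t.shape, precision="double", pad_to=bigger)
        assert sp_big.padded_shape != sp_min.padded_shape
        a = masked_ncc(sp_min, t).scores
        b = masked_ncc(sp_big, t).scores
        assert np.abs(a - b).max() < 1e-6

    def test_flat_template_rejected_at_construction(self):
        with pytest.raises(ValueError, match="flat"):
            TemplateWithMask(image=np.ones((4, 4)), mask=np.ones((4, 4), np.uint8))

    def test_low_variance_windows_score_zero(self):
        rng = np.random.default_rng(6)
        timg = rng.normal(size=(4, 4))
        img = np.zeros((16, 16))
        img[10:14, 10:14] = timg  # the rest of the field is perfectly flat
        t = TemplateWithMask(image=timg, mask=np.ones((4, 4), np.uint8))
        sp = micrograph_spectra(Micrograph(pixels=img), (4, 4), precision="double")
        s = masked_ncc(sp, t).scores
        assert s[0, 0] == 0.0
        assert np.all(np.isfinite(s))


class TestFftAccounting:
    @pytest.mark.parametrize("n, expected", [(0, 0), (1, 7), (14630, 73152)])
    def test_count_formula(self, n, expected):
        assert fft_op_count(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fft_op_count(-1)

    @pytest.mark.parametrize("k", [1, 3, 8])
    def test_counter_matches_formula(self, k):
        """Instrumented executions over a real run equal the scheduled count."""
        rng = np.random.default_rng(7)
        mic = Micrograph(pixels=rng.normal(size=(32, 32)))
        counter = FftCounter()
        sp = micrograph_spectra(mic, (6, 6), counter)
        mask = np.ones((6, 6), np.uint8)
        for _ in range(k):
            masked_ncc(sp, TemplateWithMask(image=rng.normal(size=(6, 6)), mask=mask), counter)
        assert counter.total == fft_op_count(k)
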