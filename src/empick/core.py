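"""Masked, locally normalized cross-correlation of micrographs against templates.

The engine computes, for every placement offset ``v`` of a template inside a
micrograph, the Pearson correlation between the template and the micrograph
window at ``v``, restricted to the pixels where a binary mask is 1 (Roseman's
masked NCC).  All window sums are obtained by FFT-based linear correlation:

* the micrograph side needs two forward transforms (of the padded image ``I``
  and of ``I**2``), shared across every template of the same shape;
* each template needs two forward transforms (masked template ``T*M`` and mask
  ``M``) and three inverse transforms (the cross term, the windowed sum of
  ``I`` and the windowed sum of ``I**2``).

Transforms are dispatched through :class:`FftCounter` so the exact number of
FFT executions of a run can be audited and predicted by :func:`fft_op_count`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

__all__ = [
    "Micrograph",
    "TemplateWithMask",
    "SharedSpectra",
    "NccMap",
    "FftCounter",
    "smooth_size",
    "mean_filter",
    "micrograph_spectra",
    "masked_ncc",
    "fft_op_count",
    "IMAGE_SIDE_FORWARD_FFTS",
    "TEMPLATE_SIDE_FORWARD_FFTS",
    "TEMPLATE_SIDE_INVERSE_FFTS",
]

#: forward transforms needed to build the shared micrograph spectra (I and I^2)
IMAGE_SIDE_FORWARD_FFTS = 2
#: forward transforms per template (masked template, mask)
TEMPLATE_SIDE_FORWARD_FFTS = 2
#: inverse transforms per template (cross term, window sum, window sum of squares)
TEMPLATE_SIDE_INVERSE_FFTS = 3

#: window variance (relative to the global micrograph variance) below which a
#: score is defined as 0 rather than divided out — flat ice/carbon guard.
LOW_VARIANCE_REL_TOL = 1e-12


class FftCounter:
    """Counting dispatcher for the 2D real FFTs executed by the engine.

    Every forward/inverse transform the correlation engine performs goes
    through this object, so ``counter.total`` after a run is the exact number
    of FFT executions scheduled, comparable with :func:`fft_op_count`.
    """

    def __init__(self) -> None:
        self.forward = 0
        self.inverse = 0

    @property
    def total(self) -> int:
        return self.forward + self.inverse

    def rfft2(self, a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        self.forward += 1
        return scipy.fft.rfft2(a, s=shape, workers=1)

    def irfft2(self, a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        self.inverse += 1
        return scipy.fft.irfft2(a, s=shape, workers=1)


def _as_dtype(precision: str) -> np.dtype:
    if precision == "single":
        return np.dtype(np.float32)
    if precision == "double":
        return np.dtype(np.float64)
    raise ValueError(f"precision must be 'single' or 'double', got {precision!r}")


@dataclass(frozen=True)
class Micrograph:
    """A 2D intensity image plus grid metadata."""

    pixels: np.ndarray
    pixel_size: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("micrograph must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("micrograph contains non-finite pixels")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class TemplateWithMask:
    """One search image, its binary mask, and precomputed mask statistics.

    ``mask_area`` is the pixel count P of the mask; ``template_mean_in_mask``
    and ``template_var_in_mask`` are the mean and (biased) variance of the
    template over mask pixels, which fix the template-side term of the
    normalization once per template.
    """

    image: np.ndarray
    mask: np.ndarray
    k: int = 0
    base_id: str = ""
    angle_deg: float = 0.0
    mask_area: int = field(init=False)
    template_mean_in_mask: float = field(init=False)
    template_var_in_mask: float = field(init=False)

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float64)
        msk = np.asarray(self.mask)
        if img.shape != msk.shape:
            raise ValueError("template and mask shapes differ")
        vals = np.unique(msk)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must contain only 0 and 1")
        msk = msk.astype(np.uint8)
        area = int(msk.sum())
        if area < 2:
            raise ValueError("mask must cover at least 2 pixels")
        inside = img[msk == 1]
        mean = float(inside.mean())
        var = float(inside.var())
        if var <= 0.0:
            raise ValueError("flat template (zero variance under mask) rejected")
        object.__setattr__(self, "image", np.asarray(self.image))
        object.__setattr__(self, "mask", msk)
        object.__setattr__(self, "mask_area", area)
        object.__setattr__(self, "template_mean_in_mask", mean)
        object.__setattr__(self, "template_var_in_mask", var)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass(frozen=True)
class SharedSpectra:
    """Forward spectra of one micrograph, reusable across all templates."""

    padded_shape: tuple[int, int]
    spectrum_I: np.ndarray
    spectrum_I2: np.ndarray
    fft_count: int
    image_shape: tuple[int, int]
    template_shape: tuple[int, int]
    global_variance: float
    dtype: np.dtype


@dataclass(frozen=True)
class NccMap:
    """Correlation scores over all valid placements of template ``k``."""

    scores: np.ndarray
    k: int
    valid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.scores.shape != tuple(self.valid_shape):
            raise ValueError("scores shape does not match valid_shape")


def smooth_size(n: int) -> int:
    """Smallest integer ``m >= n`` whose prime factors are all in {2, 3, 5, 7}.

    FFTs run fastest at such sizes, so padded transform dimensions are rounded
    up to the next 7-smooth length.
    """
    if n < 1:
        raise ValueError(f"size must be positive, got {n}")
    m = int(n)
    while True:
        r = m
        for p in (2, 3, 5, 7):
            while r % p == 0:
                r //= p
        if r == 1:
            return m
        m += 1


def mean_filter(image: np.ndarray, k: int) -> np.ndarray:
    """k x k boxcar average with reflect boundary; output shape == input shape.

    This is the noise-suppression pre-treatment applied to micrographs before
    correlation (default window 4).
    """
    image = np.asarray(image)
    if k < 1:
        raise ValueError(f"window size must be >= 1, got {k}")
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    if k > min(image.shape):
        raise ValueError(
            f"window {k} exceeds image dimensions {image.shape}"
        )
    from scipy.ndimage import uniform_filter

    out_dtype = image.dtype if image.dtype in (np.float32, np.float64) else np.float64
    return uniform_filter(image.astype(out_dtype, copy=False), size=k, mode="reflect")


def micrograph_spectra(
    m: Micrograph,
    template_shape: tuple[int, int],
    counter: FftCounter | None = None,
    precision: str = "single",
    pad_to: tuple[int, int] | None = None,
) -> SharedSpectra:
    """Forward-transform the (padded) micrograph and its square, once.

    The padded shape in each dimension is ``smooth_size(image + template - 1)``
    so that linear (non-circular) correlation is exact for every valid offset;
    ``pad_to`` may request any larger smooth padding (the scores are invariant
    to it).  Exactly two forward FFTs are executed; the result is shared by
    every template of ``template_shape``.
    """
    tr, tc = template_shape
    ir, ic = m.shape
    if tr > ir or tc > ic:
        raise ValueError(
            f"template {template_shape} does not fit inside micrograph {m.shape}"
        )
    dtype = _as_dtype(precision)
    counter = counter if counter is not None else FftCounter()
    padded = (smooth_size(ir + tr - 1), smooth_size(ic + tc - 1))
    if pad_to is not None:
        if pad_to[0] < padded[0] or pad_to[1] < padded[1]:
            raise ValueError(f"pad_to {pad_to} smaller than minimal padding {padded}")
        padded = (smooth_size(pad_to[0]), smooth_size(pad_to[1]))
    pixels = m.pixels.astype(dtype, copy=False)
    start = counter.total
    spec_i = counter.rfft2(pixels, padded)
    spec_i2 = counter.rfft2(pixels * pixels, padded)
    return SharedSpectra(
        padded_shape=padded,
        spectrum_I=spec_i,
        spectrum_I2=spec_i2,
        fft_count=counter.total - start,
        image_shape=(ir, ic),
        template_shape=(tr, tc),
        global_variance=float(pixels.astype(np.float64).var()),
        dtype=dtype,
    )


def masked_ncc(
    spectra: SharedSpectra,
    t: TemplateWithMask,
    counter: FftCounter | None = None,
) -> NccMap:
    """Masked NCC map of one template against the shared micrograph spectra.

    For each valid offset v (template fully inside the micrograph) the score is

        [ S_IT - S_I * S_T / P ] / sqrt( (S_I2 - S_I^2/P) * (S_T2 - S_T^2/P) )

    where the S_* are sums over mask pixels of the window/template and P is the
    mask area.  The three window sums S_IT, S_I, S_I2 come from inverse FFTs of
    products with the conjugated spectra of T*M and M.  Windows whose masked
    variance is negligible relative to the global micrograph variance score 0.
    """
    if t.shape != spectra.template_shape:
        raise ValueError(
            f"template shape {t.shape} does not match spectra "
            f"template shape {spectra.template_shape}"
        )
    dtype = spectra.dtype
    counter = counter if counter is not None else FftCounter()
    padded = spectra.padded_shape
    timg = t.image.astype(dtype, copy=False)
    tmask = t.mask.astype(dtype)

    spec_tm = counter.rfft2(timg * tmask, padded)
    spec_m = counter.rfft2(tmask, padded)

    ir, ic = spectra.image_shape
    tr, tc = spectra.template_shape
    vr, vc = ir - tr + 1, ic - tc + 1

    # correlation via conjugate product: IFFT(F_I . conj(F_A))[v] = sum_x I(x+v) A(x)
    cross = counter.irfft2(spectra.spectrum_I * np.conj(spec_tm), padded)[:vr, :vc]
    sum_i = counter.irfft2(spectra.spectrum_I * np.conj(spec_m), padded)[:vr, :vc]
    sum_i2 = counter.irfft2(spectra.spectrum_I2 * np.conj(spec_m), padded)[:vr, :vc]

    p = dtype.type(t.mask_area)
    sum_t = dtype.type(t.template_mean_in_mask * t.mask_area)
    # template-side denominator term: P * var_T = S_T2 - S_T^2 / P
    denom_t = dtype.type(np.sqrt(t.template_var_in_mask * t.mask_area))

    numer = cross - sum_i * (sum_t / p)
    var_win = sum_i2 - sum_i * sum_i / p
    np.maximum(var_win, 0, out=var_win)  # clamp FFT round-off below zero

    low_var = var_win <= dtype.type(
        LOW_VARIANCE_REL_TOL * spectra.global_variance * t.mask_area
    )
    denom = np.sqrt(var_win) * denom_t
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = numer / denom
    scores[low_var | (denom == 0)] = 0.0
    return NccMap(scores=scores.astype(dtype, copy=False), k=t.k, valid_shape=(vr, vc))


def fft_op_count(n_templates: int) -> int:
    """Total forward+inverse FFT executions for correlating ``n_templates``
    templates against one micrograph under the shared-spectrum scheme.

    The micrograph side costs ``IMAGE_SIDE_FORWARD_FFTS`` transforms once;
    every template then costs ``TEMPLATE_SIDE_FORWARD_FFTS`` forward plus
    ``TEMPLATE_SIDE_INVERSE_FFTS`` inverse transforms.  The number returned
    equals the value of an instrumented :class:`FftCounter` over the same run.
    """
    if n_templates < 0:
        raise ValueError(f"template count must be non-negative, got {n_templates}")
    if n_templates == 0:
        return 0
    per_template = TEMPLATE_SIDE_FORWARD_FFTS + TEMPLATE_SIDE_INVERSE_FFTS
    return IMAGE_SIDE_FORWARD_FFTS + per_template * n_templates
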