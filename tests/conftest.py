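"""Shared fixtures: the spatial-domain masked-correlation oracle and small
synthetic bases used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from empick import make_base_projections


def spatial_masked_ncc(img: np.ndarray, timg: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Brute-force double loop over offsets and mask pixels.

    Independent of the FFT path: every window sum is accumulated directly in
    float64.  Low-variance windows score 0, matching the engine's convention.
    """
    img = np.asarray(img, dtype=np.float64)
    ir, ic = img.shape
    tr, tc = timg.shape
    m = np.asarray(mask, dtype=bool)
    P = m.sum()
    T = np.asarray(timg, dtype=np.float64)[m]
    sT = T.sum()
    dT = np.sqrt((T * T).sum() - sT * sT / P)
    gvar = img.var()
    out = np.zeros((ir - tr + 1, ic - tc + 1))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            w = img[r : r + tr, c : c + tc][m]
            sI = w.sum()
            var_win = (w * w).sum() - sI * sI / P
            if var_win <= 1e-12 * gvar * P:
                continue
            num = (w * T).sum() - sI * sT / P
            den = np.sqrt(max(var_win, 0.0)) * dT
            out[r, c] = num / den if den > 0 else 0.0
    return out


@pytest.fixture(scope="session")
def klh_bases():
    """Side (rectangular, 2-fold) and top (circular) synthetic base views."""
    return make_base_projections()


@pytest.fixture(scope="session")
def small_bases():
    """Tiny 24-px-canvas bases for fast pipeline tests."""
    return make_base_projections(side_dims=(10, 18), top_radius=8, canvas=24)
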