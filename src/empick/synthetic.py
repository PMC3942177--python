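"""Synthetic micrographs with planted particles and exact ground truth.

The generator emulates the geometry of keyhole limpet hemocyanin (KLH) data:
rectangular "side view" projections with band texture and circular "top view"
projections with ring texture, planted at known centers and rotation angles
into a flat background with additive white Gaussian noise.  Inverted contrast
(negative amplitude, particles darker than background) is the default, which
is what makes correlation peaks negative and motivates polarity="min" picking.

Every stage of the picking pipeline can therefore be verified against the
emitted ground-truth table without any external dataset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import Micrograph, TemplateWithMask
from .templates import CIRCULAR, BaseProjection, rotate_image

__all__ = [
    "PlantSpec",
    "make_base_projections",
    "plant_particles",
    "generate_dataset",
    "noise_sigma_for_snr",
    "angle_difference",
]

#: peak signal-to-noise ratio (amplitude^2 * template variance / noise variance)
#: used to derive the default noise level — strong but visibly noisy contrast.
DEFAULT_PEAK_SNR = 25.0


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: counts, view mix, angles, contrast, noise, packing.

    ``amplitude`` scales the planted projections; negative values emulate the
    usual cryo-EM contrast (particles darker than background).  ``noise_sigma``
    of None selects the level giving peak-SNR :data:`DEFAULT_PEAK_SNR`;
    ``min_separation`` of None defaults to the template canvas size so planted
    particles never overlap.
    """

    n_particles: int = 12
    base_mix: float = 0.5
    angle_sampling: str = "grid"  # "grid" (multiples of angle_step) or "uniform"
    angle_step: float = 4.0
    amplitude: float = -1.0
    noise_sigma: float | None = None
    min_separation: float | None = None
    seed: int = 0
    max_attempts: int = 10_000


def make_base_projections(
    side_dims: tuple[int, int] = (18, 36),
    top_radius: int = 17,
    canvas: int = 48,
) -> list[BaseProjection]:
    """Fabricate the two KLH-like base views on a shared square canvas.

    The side view is a smoothed rectangle with vertical band texture and an
    exact rectangular mask (area = h*w); it has 2-fold in-plane symmetry.  The
    top view is a smoothed disk with ring texture and a disk mask; it is fully
    rotationally symmetric ("circular").  All intensity outside each mask is 0.
    """
    h, w = side_dims
    if h > canvas or w > canvas:
        raise ValueError(f"side view {side_dims} does not fit in canvas {canvas}")
    if 2 * top_radius + 1 > canvas:
        raise ValueError(f"top view radius {top_radius} does not fit in canvas {canvas}")

    rr, cc = np.mgrid[0:canvas, 0:canvas].astype(np.float64)
    center = (canvas - 1) / 2.0

    r0, c0 = (canvas - h) // 2, (canvas - w) // 2
    side_mask = np.zeros((canvas, canvas), dtype=np.uint8)
    side_mask[r0 : r0 + h, c0 : c0 + w] = 1
    # bands along the long axis, even about the canvas center -> 180-deg symmetric
    side_tex = 1.0 + 0.5 * np.cos(2.0 * np.pi * 3.0 * (cc - center) / w)
    side_img = gaussian_filter(side_tex * side_mask, 1.0) * side_mask

    dist = np.hypot(rr - center, cc - center)
    top_mask = (dist <= top_radius).astype(np.uint8)
    top_tex = 1.0 + 0.5 * np.cos(2.0 * np.pi * dist / (top_radius / 1.5))
    top_img = gaussian_filter(top_tex * top_mask, 1.0) * top_mask

    return [
        BaseProjection(image=side_img, mask=side_mask, base_id="side", symmetry=2),
        BaseProjection(image=top_img, mask=top_mask, base_id="top", symmetry=CIRCULAR),
    ]


def noise_sigma_for_snr(
    bases: list[BaseProjection], amplitude: float, snr: float = DEFAULT_PEAK_SNR
) -> float:
    """Noise sigma at which the weakest base view has the given peak-SNR.

    Peak-SNR is amplitude^2 * (template variance under the mask) / sigma^2.
    """
    var = min(
        TemplateWithMask(image=b.image, mask=b.mask).template_var_in_mask for b in bases
    )
    return float(np.sqrt(amplitude**2 * var / snr))


def _symmetry_range(base: BaseProjection) -> float:
    if base.symmetry == CIRCULAR:
        return 0.0
    return 360.0 / int(base.symmetry)


def angle_difference(a: float, b: float, symmetry: int | str) -> float:
    """Smallest angular distance between a and b modulo the base's symmetry."""
    if symmetry == CIRCULAR:
        return 0.0
    period = 360.0 / int(symmetry)
    d = (a - b) % period
    return min(d, period - d)


def plant_particles(
    canvas_shape: tuple[int, int],
    bases: list[BaseProjection],
    spec: PlantSpec,
) -> tuple[Micrograph, pd.DataFrame]:
    """Plant rotated particles into Gaussian noise; return image + truth table.

    The micrograph is a zero background plus, for each planted particle,
    ``amplitude * rotate(base, angle)`` centered at a rejection-sampled
    location (pairwise separations >= min_separation, footprint fully inside),
    plus N(0, noise_sigma^2) noise.  The truth table has one row per particle:
    center_row, center_col, base_id, angle_deg, amplitude.  Output is
    bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = bases[0].image.shape[0]
    if any(b.image.shape[0] != n for b in bases):
        raise ValueError("all base projections must share one canvas size")
    rows, cols = canvas_shape
    lo_r, hi_r = n // 2, rows - n + n // 2
    lo_c, hi_c = n // 2, cols - n + n // 2
    if hi_r < lo_r or hi_c < lo_c:
        raise ValueError(f"canvas {canvas_shape} too small for {n}x{n} particles")
    min_sep = float(spec.min_separation) if spec.min_separation is not None else float(n)
    sigma = (
        spec.noise_sigma
        if spec.noise_sigma is not None
        else noise_sigma_for_snr(bases, spec.amplitude)
    )

    centers: list[tuple[int, int]] = []
    records = []
    image = np.zeros(canvas_shape, dtype=np.float64)
    for _ in range(spec.n_particles):
        placed = False
        for _attempt in range(spec.max_attempts):
            r = int(rng.integers(lo_r, hi_r + 1))
            c = int(rng.integers(lo_c, hi_c + 1))
            if all(np.hypot(r - pr, c - pc) >= min_sep for pr, pc in centers):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.n_particles} particles with "
                f"min_separation={min_sep} in canvas {canvas_shape} "
                f"after {spec.max_attempts} attempts"
            )
        bi = 0 if (len(bases) == 1 or rng.random() < spec.base_mix) else 1
        base = bases[bi]
        rng_range = _symmetry_range(base)
        if rng_range == 0.0:
            angle = 0.0
        elif spec.angle_sampling == "grid":
            n_ang = int(round(rng_range / spec.angle_step))
            angle = float(rng.integers(0, n_ang)) * spec.angle_step
        elif spec.angle_sampling == "uniform":
            angle = float(rng.uniform(0.0, rng_range))
        else:
            raise ValueError(f"unknown angle_sampling {spec.angle_sampling!r}")
        patch = rotate_image(base.image, angle) * spec.amplitude
        image[r - n // 2 : r - n // 2 + n, c - n // 2 : c - n // 2 + n] += patch
        centers.append((r, c))
        records.append(
            {
                "center_row": r,
                "center_col": c,
                "base_id": base.base_id,
                "angle_deg": angle,
                "amplitude": spec.amplitude,
            }
        )
    if sigma > 0:
        image += rng.normal(0.0, sigma, size=canvas_shape)
    truth = pd.DataFrame.from_records(
        records,
        columns=["center_row", "center_col", "base_id", "angle_deg", "amplitude"],
    )
    return Micrograph(pixels=image.astype(np.float32), source_id="synthetic"), truth


def generate_dataset(
    out_dir: str | Path,
    n_micrographs: int,
    spec: PlantSpec,
    bases: list[BaseProjection] | None = None,
    canvas_shape: tuple[int, int] = (512, 512),
) -> dict:
    """Write a reproducible synthetic dataset to disk and return its manifest.

    Produces one MRC micrograph and one truth TSV per field, a base-projection
    MRC stack (images then masks), and a JSON manifest recording the spec, the
    per-micrograph seeds and file checksums.  Re-running with the same seed
    reproduces identical files.
    """
    from . import io as eio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bases is None:
        bases = make_base_projections()

    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(spec.seed).spawn(n_micrographs)]
    entries = []
    for i, seed in enumerate(seeds):
        mic_spec = PlantSpec(**{**asdict(spec), "seed": seed})
        mic, truth = plant_particles(canvas_shape, bases, mic_spec)
        mic_path = out / f"micrograph_{i:03d}.mrc"
        truth_path = out / f"truth_{i:03d}.tsv"
        eio.write_mrc(mic.pixels, mic_path)
        truth.to_csv(truth_path, sep="\t", index=False)
        entries.append(
            {
                "micrograph": mic_path.name,
                "truth": truth_path.name,
                "seed": seed,
                "n_particles": int(len(truth)),
                "sha256": _sha256(mic_path),
            }
        )
    base_stack = np.stack(
        [b.image.astype(np.float32) for b in bases]
        + [b.mask.astype(np.float32) for b in bases]
    )
    bases_path = out / "bases.mrc"
    eio.write_mrc(base_stack, bases_path)
    manifest = {
        "spec": asdict(spec),
        "canvas_shape": list(canvas_shape),
        "bases": bases_path.name,
        "base_ids": [b.base_id for b in bases],
        "base_symmetry": [b.symmetry for b in bases],
        "micrographs": entries,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
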