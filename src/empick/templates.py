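"""Rotation series of templates and masks from base projections.

A base projection is one noise-free 2D view of the particle (e.g. the
rectangular side view and circular top view of keyhole limpet hemocyanin)
together with a binary mask that shrink-wraps it.  The search set is built by
rotating each base through its unique angular range at a fixed step; a base
with n-fold in-plane symmetry only needs 360/n degrees of rotations, and a
circularly symmetric base needs a single template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import TemplateWithMask

__all__ = ["BaseProjection", "TemplateSet", "rotate_image", "build_rotation_series"]

CIRCULAR = "circular"


@dataclass(frozen=True)
class BaseProjection:
    """A square base view with its binary mask and in-plane symmetry order."""

    image: np.ndarray
    mask: np.ndarray
    base_id: str
    symmetry: int | str = 1  # integer order, or "circular" for full symmetry

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        msk = np.asarray(self.mask)
        if img.shape != msk.shape:
            raise ValueError("base image and mask shapes differ")
        if img.ndim != 2 or img.shape[0] != img.shape[1]:
            raise ValueError("base projection must be square so rotations stay in-frame")
        if self.symmetry != CIRCULAR and int(self.symmetry) < 1:
            raise ValueError("symmetry order must be >= 1 or 'circular'")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "mask", msk)

    def unique_range_deg(self, exploit_symmetry: bool) -> float:
        """Angular range that yields distinct views."""
        if not exploit_symmetry:
            return 360.0
        if self.symmetry == CIRCULAR:
            return 0.0
        return 360.0 / int(self.symmetry)


@dataclass(frozen=True)
class TemplateSet:
    """Ordered templates with provenance (base id, rotation angle) per index."""

    templates: tuple[TemplateWithMask, ...]
    step_deg: float
    provenance: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        shapes = {t.shape for t in self.templates}
        if len(shapes) > 1:
            raise ValueError(f"templates have mixed shapes: {shapes}")
        for i, t in enumerate(self.templates):
            if t.k != i:
                raise ValueError("template indices must be consecutive from 0")

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def __getitem__(self, k: int) -> TemplateWithMask:
        return self.templates[k]

    @property
    def template_shape(self) -> tuple[int, int]:
        return self.templates[0].shape

    def angle_of(self, k: int) -> float:
        return self.provenance[k][1]


def rotate_image(image: np.ndarray, angle_deg: float, is_mask: bool = False) -> np.ndarray:
    """Rotate a square image about its center.

    Intensity images use bilinear interpolation with 0 fill outside the
    original frame; masks are interpolated the same way and re-binarized at
    0.5 so the result is strictly {0, 1}.  Multiples of 90 degrees are exact
    index permutations (no interpolation error).
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("rotation requires a square image")
    angle = float(angle_deg) % 360.0
    if angle == 0.0:
        out = image.copy()
    elif angle % 90.0 == 0.0:
        out = np.rot90(image, k=int(angle // 90))
    else:
        out = ndimage.rotate(
            image.astype(np.float64, copy=False),
            angle,
            reshape=False,
            order=1,
            mode="constant",
            cval=0.0,
        )
    if is_mask:
        return (np.asarray(out, dtype=np.float64) >= 0.5).astype(np.uint8)
    return out


def _angles_for(base: BaseProjection, step_deg: float, exploit_symmetry: bool) -> list[float]:
    if exploit_symmetry and base.symmetry == CIRCULAR:
        return [0.0]
    rng = base.unique_range_deg(exploit_symmetry)
    n = int(round(rng / step_deg))
    return [i * step_deg for i in range(n)]


def build_rotation_series(
    bases: list[BaseProjection],
    step_deg: float = 4.0,
    exploit_symmetry: bool = False,
) -> TemplateSet:
    """Build the full template/mask search set from base projections.

    Without symmetry each base contributes ``360/step_deg`` templates at
    angles 0, step, 2*step, ...; with ``exploit_symmetry`` a base of order s
    contributes ``(360/s)/step_deg`` and a circular base exactly 1.  Template
    index k enumerates bases in input order, angles ascending — a
    deterministic ordering independent of any execution parallelism.
    """
    if not bases:
        raise ValueError("at least one base projection is required")
    n_steps = 360.0 / step_deg
    if abs(n_steps - round(n_steps)) > 1e-9 or step_deg <= 0:
        lo = 360.0 / max(1, round(n_steps))
        raise ValueError(
            f"step_deg {step_deg} must divide 360 evenly; nearest valid step is {lo:g}"
        )
    templates: list[TemplateWithMask] = []
    provenance: list[tuple[str, float]] = []
    k = 0
    for base in bases:
        for angle in _angles_for(base, step_deg, exploit_symmetry):
            img = rotate_image(base.image, angle, is_mask=False)
            msk = rotate_image(base.mask, angle, is_mask=True)
            templates.append(
                TemplateWithMask(
                    image=img, mask=msk, k=k, base_id=base.base_id, angle_deg=angle
                )
            )
            provenance.append((base.base_id, angle))
            k += 1
    return TemplateSet(
        templates=tuple(templates), step_deg=step_deg, provenance=tuple(provenance)
    )
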