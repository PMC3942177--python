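"""Peak extraction (threshold + non-maximum suppression) and pick evaluation.

A pick is called wherever the global correlation map has a local extremum
beyond a threshold.  With ``polarity="min"`` (the cryo-EM default, where
particles are darker than the background and correlation peaks are negative,
e.g. calling minima below -0.3) the map is negated internally so extraction is
always "maxima above |threshold|".  Candidates are taken in score order and
accepted greedily, suppressing later candidates within a Euclidean exclusion
radius.  Evaluation against reference coordinates uses greedy one-to-one
nearest-first matching and reports precision/recall/FDR/F-measure and the mean
matched distance, plus cumulative ROC-style true-positive counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .reduction import NO_TEMPLATE, ScoreIndexMaps

__all__ = ["Pick", "PickingMetrics", "extract_peaks", "match_picks", "roc_points"]


@dataclass(frozen=True)
class Pick:
    """One called particle: center, score, winning template, implied angle."""

    center_row: int
    center_col: int
    score: float
    k: int
    angle_deg: float = float("nan")
    micrograph_id: str = ""


@dataclass(frozen=True)
class PickingMetrics:
    n_picks: int
    n_reference: int
    true_positives: int
    precision: float
    recall: float
    fdr: float
    f_measure: float
    mean_match_distance: float

    @classmethod
    def from_counts(
        cls, n_picks: int, n_reference: int, tp: int, mean_dist: float
    ) -> "PickingMetrics":
        precision = tp / n_picks if n_picks else 0.0
        recall = tp / n_reference if n_reference else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        return cls(
            n_picks=n_picks,
            n_reference=n_reference,
            true_positives=tp,
            precision=precision,
            recall=recall,
            fdr=1.0 - precision,
            f_measure=f,
            mean_match_distance=mean_dist,
        )


def extract_peaks(
    maps: ScoreIndexMaps,
    threshold: float,
    polarity: str = "min",
    min_distance: int = 1,
    template_shape: tuple[int, int] = (1, 1),
    micrograph_id: str = "",
    template_set=None,
) -> list[Pick]:
    """Call picks from global score/index maps.

    Candidates are local maxima of the (polarity-normalized) map in a
    ``(2*min_distance+1)**2`` neighborhood with score at or beyond the
    threshold; they are then accepted greedily in descending score order
    (ties broken by row, then column), suppressing any later candidate within
    Euclidean distance ``min_distance`` of an accepted pick.  Reported centers
    are the map offset plus half the template shape, and scores keep the sign
    of the original map.
    """
    if min_distance < 1:
        raise ValueError(f"min_distance must be >= 1, got {min_distance}")
    if polarity == "min":
        if threshold > 0:
            raise ValueError(
                f"polarity='min' calls minima below a non-positive threshold; "
                f"got {threshold} (did you mean {-threshold}?)"
            )
        work = -maps.ncc
        thr = -threshold
    elif polarity == "max":
        if threshold < 0:
            raise ValueError(
                f"polarity='max' calls maxima above a non-negative threshold; "
                f"got {threshold} (did you mean {-threshold}?)"
            )
        work = maps.ncc
        thr = threshold
    else:
        raise ValueError(f"polarity must be 'min' or 'max', got {polarity!r}")

    size = 2 * min_distance + 1
    local_max = work == ndimage.maximum_filter(work, size=size, mode="nearest")
    cand = np.argwhere(local_max & (work >= thr) & (maps.ind != NO_TEMPLATE))
    if cand.size == 0:
        return []
    strength = work[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -strength))
    cand = cand[order]
    strength = strength[order]

    accepted: list[tuple[int, int]] = []
    picks: list[Pick] = []
    tr, tc = template_shape
    nrows = maps.ncc.shape[0] + tr - 1
    ncols = maps.ncc.shape[1] + tc - 1
    md2 = float(min_distance) ** 2
    for (r, c), s in zip(cand, strength):
        if any((r - ar) ** 2 + (c - ac) ** 2 <= md2 for ar, ac in accepted):
            continue
        if r + tr > nrows or c + tc > ncols:  # footprint must stay in-frame
            continue
        accepted.append((int(r), int(c)))
        k = int(maps.ind[r, c])
        angle = float(template_set.angle_of(k)) if template_set is not None else float("nan")
        picks.append(
            Pick(
                center_row=int(r) + tr // 2,
                center_col=int(c) + tc // 2,
                score=float(maps.ncc[r, c]),
                k=k,
                angle_deg=angle,
                micrograph_id=micrograph_id,
            )
        )
    return picks


def _pairwise_matches(
    pick_xy: np.ndarray, ref_xy: np.ndarray, tol: float
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching by ascending distance within tol."""
    if len(pick_xy) == 0 or len(ref_xy) == 0:
        return []
    d = np.hypot(
        pick_xy[:, 0:1] - ref_xy[None, :, 0], pick_xy[:, 1:2] - ref_xy[None, :, 1]
    )
    pairs = np.argwhere(d <= tol)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_p: set[int] = set()
    used_r: set[int] = set()
    out = []
    for i, j in pairs[order]:
        if i in used_p or j in used_r:
            continue
        used_p.add(int(i))
        used_r.add(int(j))
        out.append((int(i), int(j), float(d[i, j])))
    return out


def match_picks(
    picks: list[Pick], reference: np.ndarray, tol: float
) -> PickingMetrics:
    """Score picks against reference centers (rows of (row, col) pixels).

    Matching is greedy one-to-one by ascending distance; each pick matches at
    most one reference within ``tol``.  Precision and recall default to 0 on
    empty denominators; the mean distance is over matched pairs only (NaN when
    nothing matched).
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    ref = np.atleast_2d(np.asarray(reference, dtype=float)) if len(reference) else np.empty((0, 2))
    pk = np.array([[p.center_row, p.center_col] for p in picks], dtype=float)
    matches = _pairwise_matches(pk, ref, tol)
    tp = len(matches)
    mean_dist = float(np.mean([m[2] for m in matches])) if matches else float("nan")
    return PickingMetrics.from_counts(len(picks), len(ref), tp, mean_dist)


def roc_points(
    ranked_picks: list[Pick], reference: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Cumulative true-positive counts along the ranked pick list.

    ``ranked_picks`` must be sorted strongest-first in the configured polarity
    (non-increasing absolute score).  Matching is incremental: each pick in
    rank order claims its nearest still-unmatched reference within ``tol``,
    so earlier matches are never retracted as the depth grows.
    """
    strengths = [abs(p.score) for p in ranked_picks]
    if any(a < b for a, b in zip(strengths, strengths[1:])):
        raise ValueError("picks must be sorted by descending score strength")
    ref = np.atleast_2d(np.asarray(reference, dtype=float)) if len(reference) else np.empty((0, 2))
    unmatched = list(range(len(ref)))
    tp = 0
    curve: list[tuple[int, int]] = []
    for depth, p in enumerate(ranked_picks, start=1):
        best_j, best_d = -1, math.inf
        for j in unmatched:
            d = math.hypot(p.center_row - ref[j, 0], p.center_col - ref[j, 1])
            if d < best_d:
                best_j, best_d = j, d
        if best_j >= 0 and best_d <= tol:
            unmatched.remove(best_j)
            tp += 1
        curve.append((depth, tp))
    return curve
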