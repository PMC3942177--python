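"""Max/argmax reduction of per-template correlation maps.

Each template's correlation map is merged into a global score map
``NCC(v) = max_k NCC_k(v)`` and an index map ``IND(v) = argmax_k NCC_k(v)``
recording which template won at each offset.  The merge operator keeps, per
pixel, the larger score; exact score ties keep the smaller template index and
the sentinel index -1 (no contribution) loses to any real one.  This makes the
merge associative and commutative, so any reduction topology — sequential
("direct") accumulation or pairwise binary-tree rounds — produces bit-identical
maps, which is what makes multi-worker runs reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import NccMap

__all__ = [
    "ScoreIndexMaps",
    "ReductionPlan",
    "identity_maps",
    "maps_from_ncc",
    "merge_pair",
    "make_plan",
    "reduce_maps",
    "topology_cost",
]

NO_TEMPLATE = -1  # sentinel index: no template contributed at this offset


@dataclass
class ScoreIndexMaps:
    """Paired global correlation (ncc) and winning-template index (ind) maps."""

    ncc: np.ndarray
    ind: np.ndarray
    n_templates_merged: int = 0

    def __post_init__(self) -> None:
        if self.ncc.shape != self.ind.shape:
            raise ValueError("ncc and ind shapes differ")
        if not np.issubdtype(self.ind.dtype, np.integer):
            raise ValueError("ind must be an integer array")

    def copy(self) -> "ScoreIndexMaps":
        return ScoreIndexMaps(self.ncc.copy(), self.ind.copy(), self.n_templates_merged)


def identity_maps(shape: tuple[int, int], dtype=np.float32) -> ScoreIndexMaps:
    """The merge identity: all scores -inf, all indices the -1 sentinel."""
    return ScoreIndexMaps(
        ncc=np.full(shape, -np.inf, dtype=dtype),
        ind=np.full(shape, NO_TEMPLATE, dtype=np.int32),
        n_templates_merged=0,
    )


def maps_from_ncc(m: NccMap) -> ScoreIndexMaps:
    """Lift a single-template correlation map into score/index form."""
    return ScoreIndexMaps(
        ncc=m.scores.copy(),
        ind=np.full(m.scores.shape, m.k, dtype=np.int32),
        n_templates_merged=1,
    )


def _tie_key(ind: np.ndarray) -> np.ndarray:
    # sentinel must lose every tie; map -1 to a value larger than any index
    return np.where(ind == NO_TEMPLATE, np.iinfo(np.int32).max, ind)


def merge_pair(a: ScoreIndexMaps, b: ScoreIndexMaps) -> ScoreIndexMaps:
    """Elementwise max/argmax merge of two score/index map pairs.

    Pure per-pixel operation: larger score wins; on exact ties the smaller
    real template index wins and the -1 sentinel loses.
    """
    if a.ncc.shape != b.ncc.shape:
        raise ValueError(f"shape mismatch: {a.ncc.shape} vs {b.ncc.shape}")
    take_b = (b.ncc > a.ncc) | ((b.ncc == a.ncc) & (_tie_key(b.ind) < _tie_key(a.ind)))
    return ScoreIndexMaps(
        ncc=np.where(take_b, b.ncc, a.ncc),
        ind=np.where(take_b, b.ind, a.ind).astype(np.int32),
        n_templates_merged=a.n_templates_merged + b.n_templates_merged,
    )


@dataclass(frozen=True)
class ReductionPlan:
    """An in-process simulation of a distributed reduction schedule.

    ``schedule`` is an ordered list of rounds; each round is a list of
    (dst, src) merges whose sources are consumed.  ``transfers`` counts the
    sequential data movements on the critical path (direct: P-1; tree:
    ceil(log2 P)), ``rounds`` the number of rounds executed.
    """

    topology: str
    n_parts: int
    schedule: tuple[tuple[tuple[int, int], ...], ...]
    transfers: int
    rounds: int


def topology_cost(P: int, topology: str) -> tuple[int, int]:
    """(transfers, rounds) on the critical path for reducing P partial maps.

    Direct reduction merges every part into one master sequentially: P-1
    transfers in P-1 rounds.  Tree reduction halves the survivors each round:
    ceil(log2 P) transfers in as many rounds.
    """
    if P < 1:
        raise ValueError(f"need at least one part, got {P}")
    if topology == "direct":
        return P - 1, P - 1
    if topology == "tree":
        r = math.ceil(math.log2(P)) if P > 1 else 0
        return r, r
    raise ValueError(f"unknown topology {topology!r}")


def make_plan(n_parts: int, topology: str = "tree") -> ReductionPlan:
    """Build the merge schedule for ``n_parts`` partial maps."""
    transfers, rounds = topology_cost(n_parts, topology)
    schedule: list[tuple[tuple[int, int], ...]] = []
    if topology == "direct":
        schedule = [((0, j),) for j in range(1, n_parts)]
    else:
        alive = list(range(n_parts))
        while len(alive) > 1:
            rnd = []
            nxt = []
            for i in range(0, len(alive) - 1, 2):
                rnd.append((alive[i], alive[i + 1]))
                nxt.append(alive[i])
            if len(alive) % 2 == 1:
                nxt.append(alive[-1])
            schedule.append(tuple(rnd))
            alive = nxt
    return ReductionPlan(
        topology=topology,
        n_parts=n_parts,
        schedule=tuple(tuple(r) for r in schedule),
        transfers=transfers,
        rounds=rounds,
    )


def reduce_maps(
    parts: list[ScoreIndexMaps], plan: ReductionPlan | None = None
) -> ScoreIndexMaps:
    """Reduce partial maps to the global maps following a plan.

    The result is identical (bit-for-bit) to a sequential left fold of
    :func:`merge_pair` for every topology, by associativity/commutativity of
    the merge.  The executed merge count is recorded on the returned object as
    ``merge_ops`` for cost-accounting tests.
    """
    if not parts:
        raise ValueError("cannot reduce an empty list of maps")
    shapes = {p.ncc.shape for p in parts}
    if len(shapes) > 1:
        raise ValueError(f"partial maps have mixed shapes: {shapes}")
    if plan is None:
        plan = make_plan(len(parts))
    if plan.n_parts != len(parts):
        raise ValueError("plan was built for a different number of parts")
    slots: dict[int, ScoreIndexMaps] = {i: p for i, p in enumerate(parts)}
    merges = 0
    for rnd in plan.schedule:
        for dst, src in rnd:
            slots[dst] = merge_pair(slots[dst], slots.pop(src))
            merges += 1
    out = slots[min(slots)].copy()
    out.merge_ops = merges  # type: ignore[attr-defined]
    out.rounds_executed = len(plan.schedule)  # type: ignore[attr-defined]
    return out
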