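"""Batch picking over micrographs and templates with an in-process worker pool.

One producer feeds work items into a bounded queue; ``n_workers`` consumer
threads each accumulate a private partial score/index map, and the partials
are combined by the reduction module under the configured topology.  Because
the merge operator is associative and commutative with a total tie order,
final maps and picks are bit-identical for any worker count and either
partitioning scheme — per-micrograph (each worker handles whole micrographs)
or per-template (workers share the templates of each micrograph).
"""

from __future__ import annotations

import json
import logging
import queue
import threading
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import FftCounter, Micrograph, fft_op_count, masked_ncc, mean_filter, micrograph_spectra
from .peaks import Pick, extract_peaks
from .reduction import (
    ScoreIndexMaps,
    identity_maps,
    make_plan,
    maps_from_ncc,
    merge_pair,
    reduce_maps,
)
from .templates import TemplateSet

logger = logging.getLogger("empick")

__all__ = ["RunConfig", "plan_partition", "pick_micrograph", "run_pick"]


@dataclass
class RunConfig:
    """Everything a batch picking run needs."""

    micrograph_paths: list[str] = field(default_factory=list)
    template_stack: str | None = None      # MRC stack: N templates then N masks
    provenance_tsv: str | None = None      # k, base_id, angle_deg for the stack
    filter_size: int = 4
    threshold: float = -0.3
    polarity: str = "min"
    min_distance: int | None = None        # default: half the template width
    step_deg: float = 4.0
    exploit_symmetry: bool = False
    n_workers: int = 1
    partition_mode: str = "per_template"   # or "per_micrograph"
    topology: str = "tree"
    out_dir: str = "picks_out"
    seed: int = 0
    precision: str = "single"
    save_maps: bool = False
    queue_capacity: int | None = None      # default: 2 * n_workers

    def validate(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.partition_mode not in ("per_template", "per_micrograph"):
            raise ValueError(f"unknown partition_mode {self.partition_mode!r}")
        if self.polarity == "min" and self.threshold > 0:
            raise ValueError("polarity 'min' requires a non-positive threshold")
        if self.polarity == "max" and self.threshold < 0:
            raise ValueError("polarity 'max' requires a non-negative threshold")
        for p in self.micrograph_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"micrograph not found: {p}")


def plan_partition(
    n_micrographs: int, n_templates: int, n_workers: int, mode: str
) -> dict:
    """Static work assignment for a batch run.

    per_micrograph: micrographs round-robin over workers, each worker running
    all templates for its micrographs.  per_template: for each micrograph the
    template range is split into ``n_workers`` contiguous chunks balanced to
    within one template; their union is complete and disjoint.
    """
    if n_micrographs < 1 or n_templates < 1 or n_workers < 1:
        raise ValueError("micrograph, template and worker counts must all be >= 1")
    if mode == "per_micrograph":
        assignment = {
            w: [m for m in range(n_micrographs) if m % n_workers == w]
            for w in range(n_workers)
        }
        return {"mode": mode, "micrographs_by_worker": assignment}
    if mode == "per_template":
        base, extra = divmod(n_templates, n_workers)
        chunks = []
        start = 0
        for w in range(n_workers):
            size = base + (1 if w < extra else 0)
            chunks.append((start, start + size))
            start += size
        return {"mode": mode, "template_chunks": chunks}
    raise ValueError(f"unknown partition mode {mode!r}")


def _consume_templates(
    spectra,
    templates: TemplateSet,
    work_q: "queue.Queue[int | None]",
    partial: ScoreIndexMaps,
    counter: FftCounter,
    processed: list[int],
    sign: float,
) -> None:
    while True:
        k = work_q.get()
        if k is None:
            work_q.task_done()
            break
        ncc = masked_ncc(spectra, templates[k], counter)
        lifted = maps_from_ncc(ncc)
        if sign < 0:
            # polarity "min": reduce in flipped sign so max/argmax selects the
            # most negative correlation (the best-matching template for
            # inverted-contrast particles)
            lifted.ncc = -lifted.ncc
        merged = merge_pair(partial, lifted)
        partial.ncc, partial.ind = merged.ncc, merged.ind
        partial.n_templates_merged = merged.n_templates_merged
        processed.append(k)
        work_q.task_done()


def pick_micrograph(
    mic: Micrograph,
    templates: TemplateSet,
    filter_size: int = 4,
    threshold: float = -0.3,
    polarity: str = "min",
    min_distance: int | None = None,
    n_workers: int = 1,
    topology: str = "tree",
    precision: str = "single",
    queue_capacity: int | None = None,
) -> tuple[list[Pick], ScoreIndexMaps, dict]:
    """Full picking of one micrograph: filter, correlate, reduce, extract.

    Returns the picks, the global score/index maps and a stats dict with the
    FFT count, reduction merge count and the set of processed template
    indices.  The result is independent of ``n_workers``.
    """
    tshape = templates.template_shape
    if min_distance is None:
        min_distance = max(1, tshape[1] // 2)
    filtered = Micrograph(
        pixels=mean_filter(mic.pixels, filter_size),
        pixel_size=mic.pixel_size,
        source_id=mic.source_id,
    )
    counter = FftCounter()
    spectra = micrograph_spectra(filtered, tshape, counter, precision=precision)
    sign = -1.0 if polarity == "min" else 1.0

    valid = (mic.shape[0] - tshape[0] + 1, mic.shape[1] - tshape[1] + 1)
    dtype = np.float32 if precision == "single" else np.float64
    partials = [identity_maps(valid, dtype=dtype) for _ in range(n_workers)]
    counters = [FftCounter() for _ in range(n_workers)]
    processed: list[list[int]] = [[] for _ in range(n_workers)]

    capacity = queue_capacity if queue_capacity is not None else 2 * n_workers
    work_q: "queue.Queue[int | None]" = queue.Queue(maxsize=capacity)
    workers = [
        threading.Thread(
            target=_consume_templates,
            args=(
                spectra, templates, work_q, partials[w], counters[w], processed[w], sign,
            ),
        )
        for w in range(n_workers)
    ]
    for t in workers:
        t.start()
    for k in range(len(templates)):  # single producer; blocks when queue is full
        work_q.put(k)
    for _ in workers:
        work_q.put(None)
    for t in workers:
        t.join()

    plan = make_plan(n_workers, topology)
    global_maps = reduce_maps(partials, plan)
    if sign < 0:
        # restore original polarity: global map is now min_k NCC_k with
        # ind = argmin, the extremum the -0.3 threshold refers to
        np.negative(global_maps.ncc, out=global_maps.ncc)
    picks = extract_peaks(
        global_maps,
        threshold=threshold,
        polarity=polarity,
        min_distance=min_distance,
        template_shape=tshape,
        micrograph_id=mic.source_id,
        template_set=templates,
    )
    stats = {
        "fft_count": counter.total + sum(c.total for c in counters),
        "fft_expected": fft_op_count(len(templates)),
        "merge_ops": int(getattr(global_maps, "merge_ops", 0)),
        "reduction_rounds": int(getattr(global_maps, "rounds_executed", 0)),
        "processed_templates": sorted(k for lst in processed for k in lst),
        "n_workers": n_workers,
    }
    return picks, global_maps, stats


def _load_templates(config: RunConfig) -> TemplateSet:
    from . import io as eio
    from .core import TemplateWithMask

    if config.template_stack is None:
        raise ValueError("RunConfig.template_stack is required for run_pick")
    stack = eio.read_mrc(config.template_stack)
    if stack.ndim != 3 or stack.shape[0] % 2 != 0:
        raise ValueError(
            "template stack must hold N template images followed by N masks"
        )
    n = stack.shape[0] // 2
    prov: list[tuple[str, float]] = [("", float("nan"))] * n
    if config.provenance_tsv is not None:
        import pandas as pd

        df = pd.read_csv(config.provenance_tsv, sep="\t")
        prov = [(str(r.base_id), float(r.angle_deg)) for r in df.itertuples()]
    templates = tuple(
        TemplateWithMask(
            image=stack[i],
            mask=np.rint(stack[n + i]).astype(np.uint8),
            k=i,
            base_id=prov[i][0],
            angle_deg=prov[i][1],
        )
        for i in range(n)
    )
    return TemplateSet(templates=templates, step_deg=config.step_deg, provenance=tuple(prov))


def run_pick(config: RunConfig, templates: TemplateSet | None = None) -> dict:
    """Run picking over all configured micrographs; return the run manifest.

    An unreadable micrograph is logged and skipped (``n_failed`` in the
    manifest counts them); a template/mask inconsistency aborts before any
    micrograph is processed.  Pick tables (.tsv and .box) are written per
    micrograph under ``config.out_dir`` along with a machine-readable
    ``run_manifest.json``.
    """
    from . import io as eio

    config.validate()
    if templates is None:
        templates = _load_templates(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_workers = config.n_workers
    per_mic_workers = 1 if config.partition_mode == "per_micrograph" else n_workers

    results: dict[str, dict] = {}
    errors: dict[str, str] = {}
    lock = threading.Lock()

    def process_one(path: str) -> None:
        name = Path(path).stem
        try:
            pixels = eio.read_image(path)
            mic = Micrograph(pixels=pixels, source_id=name)
            picks, maps, stats = pick_micrograph(
                mic,
                templates,
                filter_size=config.filter_size,
                threshold=config.threshold,
                polarity=config.polarity,
                min_distance=config.min_distance,
                n_workers=per_mic_workers,
                topology=config.topology,
                precision=config.precision,
                queue_capacity=config.queue_capacity,
            )
        except Exception as exc:  # crash isolation: one bad file, not the batch
            logger.error("failed to process %s: %s", path, exc)
            with lock:
                errors[name] = str(exc)
            return
        eio.write_picks_tsv(picks, out / f"{name}_picks.tsv")
        eio.write_box(picks, out / f"{name}.box", box_size=templates.template_shape[1])
        if config.save_maps:
            eio.save_score_maps(maps, out / f"{name}", meta={"micrograph": name})
        logger.info("%s: %d picks (%d FFTs)", name, len(picks), stats["fft_count"])
        with lock:
            results[name] = {
                "n_picks": len(picks),
                "fft_count": stats["fft_count"],
                "merge_ops": stats["merge_ops"],
                "n_templates": len(templates),
            }

    if config.partition_mode == "per_micrograph" and n_workers > 1:
        mic_q: "queue.Queue[str | None]" = queue.Queue(maxsize=2 * n_workers)

        def mic_worker() -> None:
            while True:
                p = mic_q.get()
                if p is None:
                    break
                process_one(p)

        threads = [threading.Thread(target=mic_worker) for _ in range(n_workers)]
        for t in threads:
            t.start()
        for p in config.micrograph_paths:
            mic_q.put(p)
        for _ in threads:
            mic_q.put(None)
        for t in threads:
            t.join()
    else:
        for p in config.micrograph_paths:
            process_one(p)

    manifest = {
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "n_templates": len(templates),
        "micrographs": {k: results[k] for k in sorted(results)},
        "errors": {k: errors[k] for k in sorted(errors)},
        "n_processed": len(results),
        "n_failed": len(errors),
    }
    with open(out / "run_manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
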