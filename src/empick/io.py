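"""File formats: MRC images/stacks, raster fixtures, pick tables, score maps.

MRC2014 reading and writing goes through SimpleITK's MRC image IO (mode 2,
float32, on output).  Toy fixtures may also be plain TIFF/PNG rasters.  Picks
are written both as EMAN-style .box files and as a TSV table; reference
coordinates are read from the same TSV dialect or from two-column x/y text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .peaks import Pick
from .reduction import ScoreIndexMaps

__all__ = [
    "read_mrc",
    "write_mrc",
    "read_image",
    "write_box",
    "write_picks_tsv",
    "read_picks_tsv",
    "read_coords",
    "save_score_maps",
    "load_score_maps",
]

PICK_COLUMNS = ["micrograph_id", "center_col", "center_row", "score", "k", "angle_deg"]


def read_mrc(path: str | Path) -> np.ndarray:
    """Read an MRC image or stack; 2D arrays come back squeezed to 2D."""
    arr = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    return arr


def write_mrc(array: np.ndarray, path: str | Path) -> None:
    """Write a 2D image or 3D stack as MRC mode 2 (float32)."""
    arr = np.ascontiguousarray(np.asarray(array), dtype=np.float32)
    sitk.WriteImage(sitk.GetImageFromArray(arr), str(path))


def read_image(path: str | Path) -> np.ndarray:
    """Read a micrograph from MRC or a common raster format as float32."""
    path = Path(path)
    if path.suffix.lower() in {".mrc", ".mrcs", ".map"}:
        return read_mrc(path).astype(np.float32)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path)).astype(np.float32)
    if arr.ndim == 3:  # collapse RGB(A) fixtures to grayscale
        arr = arr[..., :3].mean(axis=-1)
    return arr


def write_box(picks: list[Pick], path: str | Path, box_size: int) -> None:
    """EMAN-style .box: x - box/2, y - box/2, box, box (x=column, y=row)."""
    with open(path, "w") as f:
        for p in picks:
            f.write(
                f"{p.center_col - box_size // 2}\t{p.center_row - box_size // 2}"
                f"\t{box_size}\t{box_size}\n"
            )


def write_picks_tsv(picks: list[Pick], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "micrograph_id": p.micrograph_id,
                "center_col": p.center_col,
                "center_row": p.center_row,
                "score": p.score,
                "k": p.k,
                "angle_deg": p.angle_deg,
            }
            for p in picks
        ],
        columns=PICK_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_picks_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_coords(path: str | Path) -> np.ndarray:
    """Reference centers as (row, col) rows, from pick TSV or x/y text.

    Accepts the pick-TSV dialect (columns center_row/center_col), a truth
    table from the synthetic generator, or whitespace-separated two-column
    x y (i.e. col row) text.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
        if {"center_row", "center_col"} <= set(df.columns):
            return df[["center_row", "center_col"]].to_numpy(dtype=float)
    except Exception:
        pass
    xy = np.loadtxt(path, ndmin=2)
    if xy.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns of coordinates")
    return xy[:, [1, 0]].astype(float)


def write_template_stack(template_set, stack_path: str | Path, tsv_path: str | Path) -> None:
    """Write a TemplateSet as one MRC stack (N images then N masks) + TSV.

    The TSV records provenance per index: k, base_id, angle_deg.
    """
    imgs = [t.image.astype(np.float32) for t in template_set]
    msks = [t.mask.astype(np.float32) for t in template_set]
    write_mrc(np.stack(imgs + msks), stack_path)
    df = pd.DataFrame(
        [
            {"k": t.k, "base_id": t.base_id, "angle_deg": t.angle_deg}
            for t in template_set
        ]
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def save_score_maps(maps: ScoreIndexMaps, prefix: str | Path, meta: dict | None = None) -> None:
    """Serialize maps as two MRC images plus a JSON sidecar.

    Scores are float32; indices are stored as float32 MRC (MRC2014 has no
    32-bit integer mode) and restored exactly on load since template indices
    are small integers.
    """
    prefix = Path(prefix)
    write_mrc(maps.ncc.astype(np.float32), prefix.with_suffix(".scores.mrc"))
    write_mrc(maps.ind.astype(np.float32), prefix.with_suffix(".indices.mrc"))
    sidecar = {"n_templates_merged": int(maps.n_templates_merged)}
    if meta:
        sidecar.update(meta)
    with open(prefix.with_suffix(".maps.json"), "w") as f:
        json.dump(sidecar, f, indent=2, sort_keys=True)


def load_score_maps(prefix: str | Path) -> ScoreIndexMaps:
    prefix = Path(prefix)
    ncc = read_mrc(prefix.with_suffix(".scores.mrc"))
    ind = np.rint(read_mrc(prefix.with_suffix(".indices.mrc"))).astype(np.int32)
    with open(prefix.with_suffix(".maps.json")) as f:
        sidecar = json.load(f)
    return ScoreIndexMaps(ncc=ncc, ind=ind, n_templates_merged=sidecar["n_templates_merged"])
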