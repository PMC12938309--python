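"""File I/O: image stacks with JSON sidecars, midline CSVs, cohort tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd
import tifffile

from .midline import FrameSequence, Midline

__all__ = [
    "write_frame_sequence",
    "read_frame_sequence",
    "write_midlines_csv",
    "read_midlines_csv",
]


def write_frame_sequence(seq: FrameSequence, out_dir, stem: str = "frames",
                         extra_meta: dict | None = None) -> Path:
    """Write a TIFF stack plus a JSON sidecar (dt, cm/px, metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{stem}.tif"
    tifffile.imwrite(tif, seq.frames)
    sidecar = {
        "dt_s": seq.dt,
        "cm_per_px": seq.scale,
        "n_frames": int(seq.frames.shape[0]),
        "shape": list(seq.frames.shape[1:]),
    }
    if seq.meta:
        sidecar["render"] = seq.meta
    if extra_meta:
        sidecar.update(extra_meta)
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return tif


def read_frame_sequence(out_dir, stem: str = "frames") -> FrameSequence:
    out_dir = Path(out_dir)
    frames = tifffile.imread(out_dir / f"{stem}.tif")
    with open(out_dir / f"{stem}.json") as fh:
        meta = json.load(fh)
    return FrameSequence(frames=frames, dt=meta["dt_s"],
                         scale=meta["cm_per_px"], meta=meta)


def write_midlines_csv(midlines: List[Midline], path) -> None:
    """Long-format CSV: one row per (frame, node) with t, s, x, y."""
    rows = []
    for i, m in enumerate(midlines):
        for s, (x, y) in zip(m.s_grid, m.points):
            rows.append((i, m.t, s, x, y, m.L_measured))
    pd.DataFrame(rows, columns=["frame", "t", "s", "x", "y", "L_measured"]) \
        .to_csv(path, index=False)


def read_midlines_csv(path) -> List[Midline]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("frame", sort=True):
        out.append(Midline(
            t=float(grp.t.iloc[0]),
            points=grp[["x", "y"]].to_numpy(),
            s_grid=grp.s.to_numpy(),
            L_measured=float(grp.L_measured.iloc[0]),
        ))
    return out
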