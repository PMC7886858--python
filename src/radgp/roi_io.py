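"""Reading ROI image stacks and writing feature tables.

A stack on disk is one file per MRI contrast, named ``<Contrast>.nii`` /
``<Contrast>.nii.gz`` (NIfTI, via nibabel) or ``<Contrast>.csv`` (a plain
numeric grid).  NIfTI volumes with a trailing singleton dimension are
squeezed to 2-D.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CONTRASTS
from .textures import TextureConfig, extract_all


def read_roi_stack(indir) -> dict:
    """Load a 6-contrast stack from a directory of NIfTI or CSV grids."""
    indir = Path(indir)
    if not indir.is_dir():
        raise FileNotFoundError(f"ROI stack directory not found: {indir}")
    stack = {}
    for c in CONTRASTS:
        csv = indir / f"{c}.csv"
        niis = [indir / f"{c}.nii", indir / f"{c}.nii.gz"]
        if csv.exists():
            stack[c] = np.loadtxt(csv, delimiter=",", ndmin=2)
        else:
            nii = next((p for p in niis if p.exists()), None)
            if nii is None:
                raise FileNotFoundError(f"no {c}.csv or {c}.nii[.gz] in {indir}")
            import nibabel as nib

            arr = np.asarray(nib.load(str(nii)).dataobj, dtype=float)
            stack[c] = np.squeeze(arr)
        if stack[c].ndim != 2:
            raise ValueError(f"contrast {c} is not a 2-D grid: shape {stack[c].shape}")
    return stack


def write_roi_stack(stack: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c, arr in stack.items():
        np.savetxt(outdir / f"{c}.csv", np.asarray(arr, dtype=float), delimiter=",")


def extract_feature_table(
    stacks: dict, config: TextureConfig | None = None
) -> pd.DataFrame:
    """Feature table (one row per stack ID) with Table-style column names."""
    rows = {}
    for sid, stack in stacks.items():
        rows[sid] = extract_all(stack, config).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df.reset_index()
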