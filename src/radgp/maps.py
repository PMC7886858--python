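"""Spatial prediction maps over sliding-window texture features.

Given a trained model and a 6-contrast image (one 2-D array per contrast),
the renderer slides an 8x8 window over the image, extracts the 336-feature
texture vector at every position, and predicts class and z-test p-value per
window.  Windows are indexed by their top-left voxel (row-major, origin
top-left, 0-based); the map has shape (H - 8 + 1) x (W - 8 + 1) at stride 1.
Windows with p >= 0.05 are flagged low-certainty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnv import CNV_THRESHOLD
from .gp import GPModel
from .synthetic import CONTRASTS
from .textures import WINDOW_SIZE, TextureConfig, extract_all
from .uncertainty import P_CUTOFF, assess


def render_map(
    image_stack: dict,
    model: GPModel,
    stride: int = 1,
    *,
    texture_config: TextureConfig | None = None,
    threshold: float = CNV_THRESHOLD,
) -> pd.DataFrame:
    """Per-window predictions over a multi-contrast image.

    Returns a table with columns row, col, mean, sd, p_value, predicted_class,
    low_certainty; rows are in row-major window order.
    """
    missing = [c for c in CONTRASTS if c not in image_stack]
    if missing:
        raise ValueError(f"missing contrast(s): {', '.join(missing)}")
    shapes = {np.asarray(image_stack[c]).shape for c in CONTRASTS}
    if len(shapes) != 1:
        raise ValueError(f"contrast images differ in shape: {shapes}")
    (H, W) = shapes.pop()
    if H < WINDOW_SIZE or W < WINDOW_SIZE:
        raise ValueError(f"image {H}x{W} smaller than the {WINDOW_SIZE}x{WINDOW_SIZE} window")

    rows = []
    for r in range(0, H - WINDOW_SIZE + 1, stride):
        for c in range(0, W - WINDOW_SIZE + 1, stride):
            window_stack = {
                name: np.asarray(image_stack[name], dtype=float)[r : r + WINDOW_SIZE, c : c + WINDOW_SIZE]
                for name in CONTRASTS
            }
            fv = extract_all(window_stack, texture_config)
            dist = model.predict_one(np.asarray(fv.values))
            ua = assess(dist, threshold)
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "mean": dist.mean,
                    "sd": ua.sd,
                    "p_value": ua.p_value,
                    "predicted_class": ua.predicted_class,
                    "low_certainty": ua.p_value >= P_CUTOFF,
                }
            )
    return pd.DataFrame(rows)


def map_shape(image_shape: tuple, stride: int = 1) -> tuple:
    """Grid dimensions of a rendered map: image minus window footprint + 1."""
    H, W = image_shape
    return (
        (H - WINDOW_SIZE) // stride + 1,
        (W - WINDOW_SIZE) // stride + 1,
    )
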