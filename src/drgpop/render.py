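"""Render simulated traces to a multi-frame image stack with an ROI table.

Each cell is drawn as a disc whose pixel area approximates its soma area
under a declared um/px scale (default 2 um/px, i.e. a 700 um^2 soma spans
~15 px diameter in a 512x512 field). Disc pixels carry the cell's raw trace
value for that frame; everything else is background. A dedicated cell-free
background disc is reserved so that ROI extraction can background-subtract.

Frames are quantized to uint16 (standard for microscopy TIFFs), so recovered
trace values carry at most +-0.5 a.u. rounding error.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import PlacementError, ValidationError
from .traces import FluorescenceTrace, _disc_mask

DEFAULT_UM_PER_PX = 2.0
BACKGROUND_ROI_RADIUS_PX = 10.0
_PLACEMENT_MARGIN_PX = 2.0


def render_image_stack(
    traces: Sequence[FluorescenceTrace],
    areas_um2: Sequence[float],
    field_size_px: int = 512,
    um_per_px: float = DEFAULT_UM_PER_PX,
    background_level: float = 0.0,
    background_noise_sd: float = 0.0,
    seed: int | None = None,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, pd.DataFrame, tuple[float, float, float]]:
    """Draw all cells into a (frames, H, W) uint16 stack.

    Returns ``(stack, roi_table, background_roi)`` where the ROI table has
    columns ``cell_id, x_px, y_px, radius_px`` and ``background_roi`` is the
    ``(x, y, radius)`` of the reserved cell-free disc.

    Raises :class:`PlacementError` when the field cannot hold all somata
    without overlap.
    """
    if len(traces) != len(areas_um2):
        raise ValidationError("need one area per trace")
    lengths = {t.values.size for t in traces}
    if len(lengths) > 1:
        raise ValidationError("all traces must share the same frame count")
    rates = {t.sampling_rate for t in traces}
    if len(rates) > 1:
        raise ValidationError("all traces must share the sampling rate")
    n_frames = lengths.pop() if lengths else 1

    rng = np.random.default_rng(seed)
    radii = [math.sqrt(a / math.pi) / um_per_px for a in areas_um2]

    placed: list[tuple[float, float, float]] = []

    def place(radius: float) -> tuple[float, float]:
        for _ in range(max_attempts):
            x = rng.uniform(radius + 1, field_size_px - radius - 2)
            y = rng.uniform(radius + 1, field_size_px - radius - 2)
            ok = all(
                math.hypot(x - px, y - py) > radius + pr + _PLACEMENT_MARGIN_PX
                for px, py, pr in placed
            )
            if ok:
                placed.append((x, y, radius))
                return x, y
        raise PlacementError(
            f"could not place a disc of radius {radius:.1f} px in a "
            f"{field_size_px}x{field_size_px} field"
        )

    bg_x, bg_y = place(BACKGROUND_ROI_RADIUS_PX)
    background_roi = (bg_x, bg_y, BACKGROUND_ROI_RADIUS_PX)

    rows = []
    masks = []
    for tr, radius in zip(traces, radii):
        x, y = place(radius)
        rows.append(
            {"cell_id": tr.cell_id, "x_px": x, "y_px": y, "radius_px": radius}
        )
        masks.append(_disc_mask((field_size_px, field_size_px), x, y, radius))
    roi_table = pd.DataFrame(rows, columns=["cell_id", "x_px", "y_px", "radius_px"])

    stack = np.full(
        (n_frames, field_size_px, field_size_px), float(background_level)
    )
    if background_noise_sd > 0:
        stack += rng.normal(0.0, background_noise_sd, stack.shape)
    for tr, mask in zip(traces, masks):
        stack[:, mask] = tr.values[:, None]
    return np.clip(np.rint(stack), 0, 65535).astype(np.uint16), roi_table, background_roi


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, stack)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
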