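"""Raw fluorescence to normalized dF/F and epoch-averaged features.

The processing chain mirrors the standard in vivo calcium-imaging workflow:
per-cell raw traces (from a trace table or from ROI extraction over an image
stack) are normalized to the pre-stimulus baseline as

    dF/F (%) = 100 * (F - F0) / F0,   F0 = mean F over the baseline epoch,

and then reduced to one feature per stimulation epoch: the mean dF/F over
all frames of that epoch. The baseline SD (in the same % units) is retained
per cell because the responder criterion adds a multiple of it to a fixed
% threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateBaselineError, ValidationError
from .protocol import Epoch, StimulusProtocol

log = logging.getLogger(__name__)

MIN_BASELINE_FRAMES = 8


@dataclass
class FluorescenceTrace:
    """One cell's raw fluorescence time series (arbitrary units)."""

    cell_id: str
    values: np.ndarray
    sampling_rate: float
    source: str = "table"  # table | roi_extraction | synthetic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValidationError(f"trace {self.cell_id!r}: empty values")
        if self.sampling_rate <= 0:
            raise ValidationError(f"trace {self.cell_id!r}: non-positive sampling rate")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


@dataclass
class DffTrace:
    """Baseline-normalized trace in % dF/F with its baseline statistics."""

    cell_id: str
    values: np.ndarray
    sampling_rate: float
    baseline_mean_F0: float
    baseline_sd_pct: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


def compute_dff(trace: FluorescenceTrace, baseline_epoch: Epoch) -> DffTrace:
    """Normalize a raw trace to its baseline-epoch mean.

    Raises
    ------
    DegenerateBaselineError
        If the baseline mean F0 is non-positive (e.g. after background
        subtraction); such cells are meant to be excluded and logged by the
        caller rather than clipped.
    ValidationError
        If fewer than 8 frames fall inside the baseline epoch.
    """
    t = trace.times
    mask = (t >= baseline_epoch.start) & (t < baseline_epoch.end)
    n_base = int(mask.sum())
    if n_base < MIN_BASELINE_FRAMES:
        raise ValidationError(
            f"cell {trace.cell_id!r}: baseline epoch covers only {n_base} frames "
            f"(need >= {MIN_BASELINE_FRAMES})"
        )
    f0 = float(trace.values[mask].mean())
    if f0 <= 0:
        raise DegenerateBaselineError(
            f"cell {trace.cell_id!r}: baseline mean F0 = {f0:.3g} <= 0"
        )
    dff = 100.0 * (trace.values - f0) / f0
    sd = float(np.std(dff[mask], ddof=1))
    return DffTrace(
        cell_id=trace.cell_id,
        values=dff,
        sampling_rate=trace.sampling_rate,
        baseline_mean_F0=f0,
        baseline_sd_pct=sd,
    )


def compute_dff_population(
    traces: Iterable[FluorescenceTrace], baseline_epoch: Epoch
) -> tuple[list[DffTrace], list[str]]:
    """Normalize many cells; degenerate-baseline cells are dropped and logged."""
    out: list[DffTrace] = []
    excluded: list[str] = []
    for tr in traces:
        try:
            out.append(compute_dff(tr, baseline_epoch))
        except DegenerateBaselineError as exc:
            log.warning("excluding cell: %s", exc)
            excluded.append(tr.cell_id)
    return out, excluded


def epoch_average(dff: DffTrace, protocol: StimulusProtocol) -> np.ndarray:
    """Mean dF/F per stimulation epoch (baseline excluded), in protocol order."""
    needed = math.ceil(protocol.epochs[-1].end * dff.sampling_rate)
    if dff.values.size < needed:
        raise ValidationError(
            f"cell {dff.cell_id!r}: trace has {dff.values.size} frames but protocol "
            f"requires {needed}"
        )
    t = dff.times
    means = np.empty(len(protocol.stimulation_epochs))
    for j, ep in enumerate(protocol.stimulation_epochs):
        mask = (t >= ep.start) & (t < ep.end)
        means[j] = dff.values[mask].mean()
    return means


@dataclass
class FeatureMatrix:
    """Cells x stimulation-epochs matrix of epoch-mean dF/F (%)."""

    cell_ids: list[str]
    epoch_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.epoch_labels)):
            raise ValidationError("feature matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValidationError("feature matrix contains missing values")

    def row(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]

    def subset(self, cell_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return FeatureMatrix(list(cell_ids), list(self.epoch_labels), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.epoch_labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="cell_id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, index_col="cell_id"))


def build_feature_matrix(
    dffs: Sequence[DffTrace], protocol: StimulusProtocol
) -> FeatureMatrix:
    values = np.vstack([epoch_average(d, protocol) for d in dffs]) if dffs else np.empty((0, len(protocol.stimulation_epochs)))
    return FeatureMatrix(
        [d.cell_id for d in dffs], list(protocol.stimulation_labels), values
    )


# ---------------------------------------------------------------------------
# ROI extraction from image stacks


def _disc_mask(shape: tuple[int, int], x: float, y: float, radius: float) -> np.ndarray:
    # pixel belongs to the disc when its centre lies within the radius
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - x) ** 2 + (yy - y) ** 2 <= radius**2


def extract_roi_traces(
    image_stack: np.ndarray,
    roi_table: pd.DataFrame,
    background_roi: tuple[float, float, float],
    sampling_rate: float,
) -> list[FluorescenceTrace]:
    """Per-frame disc-ROI means with background subtraction.

    Parameters
    ----------
    image_stack
        Array of shape (frames, height, width).
    roi_table
        Columns ``cell_id, x_px, y_px, radius_px``.
    background_roi
        ``(x_px, y_px, radius_px)`` of a cell-free background disc; its
        per-frame mean is subtracted from every cell ROI's mean.
    """
    if image_stack.ndim != 3:
        raise ValidationError("image stack must be (frames, height, width)")
    h, w = image_stack.shape[1:]

    bx, by, br = background_roi
    bg_mask = _disc_mask((h, w), bx, by, br)
    if not bg_mask.any():
        raise ValidationError("background ROI contains no pixels")
    _check_in_bounds("background", bx, by, br, h, w)

    masks = []
    for row in roi_table.itertuples(index=False):
        _check_in_bounds(str(row.cell_id), row.x_px, row.y_px, row.radius_px, h, w)
        m = _disc_mask((h, w), row.x_px, row.y_px, row.radius_px)
        if (m & bg_mask).any():
            raise ValidationError(
                f"background ROI overlaps cell ROI {row.cell_id!r}"
            )
        masks.append((str(row.cell_id), m))

    flat = image_stack.reshape(image_stack.shape[0], -1).astype(float)
    bg = flat[:, bg_mask.ravel()].mean(axis=1)
    out = []
    for cell_id, m in masks:
        vals = flat[:, m.ravel()].mean(axis=1) - bg
        out.append(
            FluorescenceTrace(cell_id, vals, sampling_rate, source="roi_extraction")
        )
    return out


def _check_in_bounds(name: str, x: float, y: float, r: float, h: int, w: int) -> None:
    if x - r < -0.5 or y - r < -0.5 or x + r > w - 0.5 or y + r > h - 0.5:
        raise ValidationError(f"ROI {name!r} extends outside the frame bounds")


# ---------------------------------------------------------------------------
# CSV interchange (long format: cell_id, frame, time_s, F_raw)


def traces_to_frame(traces: Sequence[FluorescenceTrace]) -> pd.DataFrame:
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": np.arange(tr.values.size),
                    "time_s": tr.times,
                    "F_raw": tr.values,
                }
            )
        )
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["cell_id", "frame", "time_s", "F_raw"]
    )


def traces_from_frame(df: pd.DataFrame, sampling_rate: float) -> list[FluorescenceTrace]:
    out = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame")
        out.append(
            FluorescenceTrace(str(cell_id), sub["F_raw"].to_numpy(), sampling_rate)
        )
    return out


def dffs_to_frame(dffs: Sequence[DffTrace]) -> pd.DataFrame:
    parts = []
    for d in dffs:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": d.cell_id,
                    "frame": np.arange(d.values.size),
                    "dff_pct": d.values,
                }
            )
        )
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["cell_id", "frame", "dff_pct"]
    )
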