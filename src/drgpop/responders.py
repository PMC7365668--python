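"""Binary responder classification and cell-size stratification.

A cell *responds* to a stimulation epoch when its epoch-mean dF/F reaches
a stringent threshold: 70% above baseline fluorescence plus 4 baseline
standard deviations (all in % dF/F units, comparison inclusive). The
fraction of responders among all imaged cells is the population-coding
readout; counts are quantified in a binary fashion over every selected ROI.

Soma areas are stratified into small (< 700 um^2), medium ([700, 1200) um^2)
and large (>= 1200 um^2) classes. Sizes and fluorescence intensities are
only analysed for responders, since a non-responder may simply lie outside
the stimulated receptive field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyFilterError, ValidationError
from .protocol import StimulusProtocol
from .traces import DffTrace, epoch_average

RESPONSE_THRESHOLD_PCT = 70.0
RESPONSE_N_SD = 4.0
SIZE_BOUNDS_UM2 = (700.0, 1200.0)
SIZE_CLASSES = ("small", "medium", "large")


def response_threshold(
    baseline_sd_pct: float,
    threshold_pct: float = RESPONSE_THRESHOLD_PCT,
    n_sd: float = RESPONSE_N_SD,
) -> float:
    """The per-cell response threshold in % dF/F: 70 + 4 * baseline SD."""
    return threshold_pct + n_sd * baseline_sd_pct


def classify_responder(
    dff: DffTrace,
    protocol: StimulusProtocol,
    *,
    threshold_pct: float = RESPONSE_THRESHOLD_PCT,
    n_sd: float = RESPONSE_N_SD,
    criterion: str = "sum",
) -> dict[str, bool]:
    """Flag each stimulation epoch of one cell as response / no response.

    ``criterion="sum"`` (default) uses the additive reading of the
    threshold: epoch-mean dF/F >= threshold_pct + n_sd * baseline SD.
    ``criterion="and"`` requires both epoch-mean >= threshold_pct and
    epoch-mean >= n_sd * baseline SD. Comparisons are inclusive.
    """
    if criterion not in ("sum", "and"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    means = epoch_average(dff, protocol)
    sd = dff.baseline_sd_pct
    flags = {}
    for label, m in zip(protocol.stimulation_labels, means):
        if criterion == "sum":
            flags[label] = bool(m >= threshold_pct + n_sd * sd)
        else:
            flags[label] = bool(m >= threshold_pct and m >= n_sd * sd)
    return flags


def classify_population(
    dffs: Sequence[DffTrace],
    protocol: StimulusProtocol,
    **kwargs,
) -> pd.DataFrame:
    """Responder-flag table: one row per cell, one boolean column per epoch,
    plus ``overall_responder`` (OR over epochs)."""
    labels = list(protocol.stimulation_labels)
    rows = []
    for d in dffs:
        flags = classify_responder(d, protocol, **kwargs)
        row = {"cell_id": d.cell_id, **flags}
        row["overall_responder"] = any(flags.values())
        rows.append(row)
    return pd.DataFrame(rows, columns=["cell_id", *labels, "overall_responder"])


def make_cell_records(
    flags: pd.DataFrame, attributes: pd.DataFrame
) -> pd.DataFrame:
    """Join responder flags with static cell attributes (area, group, tracer).

    Adds a ``size_class`` column derived from ``area_um2``.
    """
    records = attributes.merge(flags, on="cell_id", how="inner", validate="1:1")
    if "area_um2" in records:
        records["size_class"] = [size_class(a) for a in records["area_um2"]]
    return records


@dataclass
class ResponderCurve:
    """Fraction of cells responding at each stimulation epoch.

    The denominator is all filtered cells (every imaged ROI), not only
    responders. ``cumulative`` is the recruitment variant: the fraction of
    cells that responded at any epoch up to (and including) each position.
    ``cell_flags`` retains the per-cell boolean matrix so fold changes can
    be bootstrapped over cells.
    """

    epoch_labels: list[str]
    fraction: np.ndarray
    se: np.ndarray
    cumulative: np.ndarray
    n_cells: int
    cell_flags: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch_labels,
                "fraction": self.fraction,
                "se": self.se,
                "cumulative_fraction": self.cumulative,
                "n_cells": self.n_cells,
            }
        )


def responder_fraction_curve(
    cell_records: pd.DataFrame,
    epoch_labels: Sequence[str],
    group: Optional[str] = None,
    tracer: Optional[str] = None,
) -> ResponderCurve:
    """Per-epoch responder fractions with binomial SE, optionally filtered."""
    sub = cell_records
    if group is not None:
        sub = sub[sub["group"] == group]
    if tracer is not None:
        sub = sub[sub["tracer"] == tracer]
    n = len(sub)
    if n == 0:
        raise EmptyFilterError(
            f"no cells left after filtering (group={group!r}, tracer={tracer!r})"
        )
    flags = sub[list(epoch_labels)].to_numpy(dtype=bool)
    frac = flags.mean(axis=0)
    se = np.sqrt(frac * (1 - frac) / n)
    cumulative = np.maximum.accumulate(flags, axis=1).mean(axis=0)
    return ResponderCurve(
        epoch_labels=list(epoch_labels),
        fraction=frac,
        se=se,
        cumulative=cumulative,
        n_cells=n,
        cell_flags=sub[["cell_id", *epoch_labels]].reset_index(drop=True),
    )


def size_class(area_um2: float) -> str:
    """small (< 700), medium ([700, 1200)) or large (>= 1200) um^2."""
    if not area_um2 > 0:
        raise ValidationError(f"non-positive soma area: {area_um2!r}")
    lo, hi = SIZE_BOUNDS_UM2
    if area_um2 < lo:
        return "small"
    if area_um2 < hi:
        return "medium"
    return "large"


def size_distribution_by_epoch(
    cell_records: pd.DataFrame, epoch_labels: Sequence[str]
) -> pd.DataFrame:
    """Per-epoch counts of responders in each size class + mean responder area.

    Only cells flagged at an epoch contribute to that epoch's row; when no
    cell responded the mean area is emitted as missing (NaN).
    """
    if "area_um2" not in cell_records:
        raise ValidationError("cell records lack an area_um2 column")
    rows = []
    for label in epoch_labels:
        resp = cell_records[cell_records[label].astype(bool)]
        classes = resp["area_um2"].map(size_class)
        row = {"epoch": label}
        for c in SIZE_CLASSES:
            row[c] = int((classes == c).sum())
        row["mean_responder_area_um2"] = (
            float(resp["area_um2"].mean()) if len(resp) else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=["epoch", *SIZE_CLASSES, "mean_responder_area_um2"])
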