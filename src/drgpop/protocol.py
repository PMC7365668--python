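"""Mechanical stimulation protocols.

A :class:`StimulusProtocol` is an ordered list of labelled time epochs over
a recording: one pre-stimulus baseline epoch followed by stimulation epochs.
Three protocol kinds are supported, mirroring the in vivo experiments the
generator emulates:

``pressure_ramp``
    A pressure cuff inflated in 50 mm Hg increments every 10 s over
    0-400 mm Hg: eight 10 s stimulation epochs labelled ``P050`` ... ``P400``.
``movement``
    Five consecutive extension-flexion pairs of the limb, epochs labelled
    ``E1, F1, ..., E5, F5``, with rest gaps between events.
``brush``
    A single dynamic-brushing epoch.

Epoch intensities are in mm Hg for pressure epochs and ``None`` otherwise.
Frame ``k`` of a recording at ``sampling_rate`` Hz is timestamped
``k / sampling_rate``; a frame belongs to an epoch when its timestamp lies
in the half-open interval ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

PRESSURE_STEPS_MMHG: tuple[int, ...] = tuple(range(50, 401, 50))
PRESSURE_STEP_DURATION_S = 10.0
N_MOVEMENT_PAIRS = 5
SAMPLING_RATE_RANGE_HZ = (2.0, 4.0)

PROTOCOL_KINDS = ("pressure_ramp", "movement", "brush")


@dataclass(frozen=True)
class Epoch:
    """One labelled time window of a stimulation protocol."""

    label: str
    start: float
    end: float
    intensity: Optional[float] = None  # mm Hg; None for baseline/movement/brush

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"epoch {self.label!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.intensity is not None and self.intensity < 0:
            raise ValidationError(f"epoch {self.label!r}: negative intensity")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping epochs with one leading baseline epoch."""

    kind: str
    sampling_rate: float
    epochs: tuple[Epoch, ...]
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValidationError(f"unsupported protocol kind {self.kind!r}")
        lo, hi = SAMPLING_RATE_RANGE_HZ
        if not (lo <= self.sampling_rate <= hi):
            raise ValidationError(
                f"sampling rate {self.sampling_rate} Hz outside supported range [{lo}, {hi}]"
            )
        if not self.epochs or self.epochs[0].label != "baseline":
            raise ValidationError("first epoch must be labelled 'baseline'")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"epochs {a.label!r} and {b.label!r} overlap or are out of order"
                )
        if self.duration_s < self.epochs[-1].end:
            raise ValidationError("duration_s must cover all epochs")

    @property
    def baseline(self) -> Epoch:
        return self.epochs[0]

    @property
    def stimulation_epochs(self) -> tuple[Epoch, ...]:
        return self.epochs[1:]

    @property
    def stimulation_labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.stimulation_epochs)

    @property
    def n_frames(self) -> int:
        return math.ceil(self.duration_s * self.sampling_rate)

    def frame_times(self) -> np.ndarray:
        """Timestamps (s) of every frame in a recording of this protocol."""
        return np.arange(self.n_frames) / self.sampling_rate

    def frames_in(self, epoch: Epoch) -> np.ndarray:
        """Boolean mask of frames whose timestamp falls in [start, end)."""
        t = self.frame_times()
        return (t >= epoch.start) & (t < epoch.end)


def make_protocol(
    kind: str,
    sampling_rate: float = 4.0,
    baseline_duration_s: float = 20.0,
    *,
    event_duration_s: float = 5.0,
    rest_duration_s: float = 5.0,
    brush_duration_s: float = 10.0,
) -> StimulusProtocol:
    """Build a standard stimulation protocol.

    Parameters
    ----------
    kind
        ``pressure_ramp``, ``movement`` or ``brush``.
    sampling_rate
        Acquisition rate in frames/s; must lie in [2, 4].
    baseline_duration_s
        Length of the pre-stimulus baseline window (> 0).
    event_duration_s, rest_duration_s
        Movement protocols only: length of each extension/flexion event and
        of the rest gap between consecutive events.
    """
    if kind not in PROTOCOL_KINDS:
        raise ValidationError(f"unsupported protocol kind {kind!r}")
    if baseline_duration_s <= 0:
        raise ValidationError("baseline_duration_s must be positive")

    b = float(baseline_duration_s)
    epochs: list[Epoch] = [Epoch("baseline", 0.0, b)]

    if kind == "pressure_ramp":
        t = b
        for p in PRESSURE_STEPS_MMHG:
            epochs.append(Epoch(f"P{p:03d}", t, t + PRESSURE_STEP_DURATION_S, float(p)))
            t += PRESSURE_STEP_DURATION_S
        duration = t
    elif kind == "movement":
        if event_duration_s <= 0 or rest_duration_s < 0:
            raise ValidationError("movement event/rest durations must be positive")
        t = b
        for pair in range(1, N_MOVEMENT_PAIRS + 1):
            for ev in ("E", "F"):
                epochs.append(Epoch(f"{ev}{pair}", t, t + event_duration_s))
                t += event_duration_s + rest_duration_s
        duration = t
    else:  # brush
        epochs.append(Epoch("brush", b, b + brush_duration_s))
        duration = b + brush_duration_s

    return StimulusProtocol(
        kind=kind,
        sampling_rate=float(sampling_rate),
        epochs=tuple(epochs),
        duration_s=duration,
    )


def movement_event_index(label: str) -> int:
    """0-based event order of a movement epoch label (E1 -> 0, F1 -> 1, ...)."""
    ev, pair = label[0], int(label[1:])
    if ev not in ("E", "F") or pair < 1:
        raise ValidationError(f"not a movement epoch label: {label!r}")
    return (pair - 1) * 2 + (0 if ev == "E" else 1)
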