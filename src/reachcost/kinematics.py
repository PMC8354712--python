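"""Kinematic event detection on 100-Hz hand traces.

Conventions follow the recording set-up: positions in cm relative to the
start-point centre, sampled every 10 ms.  Movement onset is the first sample
outside the start circle; movement end is the first post-onset sample whose
speed drops below a stop threshold, classed as a target hit if that sample lies
inside a displayed target and as a missed-target candidate otherwise.  The
initial movement direction is summarised by the angle of the start-to-hand
vector exactly 100 ms (ten samples) after onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .design import START_RADIUS_CM, TargetSpec, PositionId
from .errors import (InconsistentEventsError, InsufficientTraceError,
                     NoMovementError, NoStopError, PreconditionError)

#: "One pixel per second" on the 20-inch 1024x768 display, in cm/s.  The pixel
#: pitch is ~0.04 cm (40.6-cm wide visible raster / 1024 px); configurable
#: because the exact raster size of the monitor is uncertain.
SPEED_THRESHOLD_CM_S = 0.04

DT_MS = 10


@dataclass(frozen=True)
class HandTrace:
    """Uniform 100-Hz 2-D hand-position series for one trial.

    ``t`` is in ms since the first auditory tone (need not start at zero),
    strictly increasing in 10-ms steps; ``x``/``y`` in cm from the start-point
    centre.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t)
        if t.ndim != 1 or len(t) != len(self.x) or len(t) != len(self.y):
            raise PreconditionError("t, x, y must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) == DT_MS):
            raise PreconditionError("trace must be uniformly sampled at 10 ms")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def radius(self) -> np.ndarray:
        """Distance of each sample from the start-point centre (cm)."""
        return np.hypot(np.asarray(self.x, float), np.asarray(self.y, float))

    def index_at(self, t_ms: float) -> int:
        idx = int(round((t_ms - self.t[0]) / DT_MS))
        if idx < 0 or idx >= len(self) or self.t[idx] != t_ms:
            raise InsufficientTraceError(f"no sample at t={t_ms} ms")
        return idx


def speed(trace: HandTrace) -> np.ndarray:
    """Per-sample speed in cm/s: central finite differences, one-sided at the ends."""
    xy = trace.xy.astype(float)
    v = np.empty(len(trace))
    dt_s = DT_MS / 1000.0
    if len(trace) == 1:
        return np.zeros(1)
    v[1:-1] = np.hypot(*(xy[2:] - xy[:-2]).T) / (2 * dt_s)
    v[0] = np.hypot(*(xy[1] - xy[0])) / dt_s
    v[-1] = np.hypot(*(xy[-1] - xy[-2])) / dt_s
    return v


def detect_onset(trace: HandTrace, start_radius: float = START_RADIUS_CM) -> int:
    """Movement onset: time of the first sample outside the start circle.

    Raises
    ------
    PreconditionError
        If the trace does not begin inside the start circle.
    NoMovementError
        If the hand never leaves the start circle.
    """
    r = trace.radius
    if r[0] > start_radius:
        raise PreconditionError("trace starts outside the start circle")
    outside = np.nonzero(r > start_radius)[0]
    if not len(outside):
        raise NoMovementError("hand never left the start circle")
    return int(trace.t[outside[0]])


@dataclass(frozen=True)
class EndEvent:
    end_ms: int
    end_xy: np.ndarray
    end_speed: float
    inside_target: Optional[PositionId]  # None -> missed-target candidate


def detect_end(trace: HandTrace, targets: Sequence[TargetSpec], onset_ms: int,
               speed_threshold: float = SPEED_THRESHOLD_CM_S) -> EndEvent:
    """Movement end: first post-onset sample with speed below the threshold.

    If that sample lies inside one of the displayed targets the movement ended
    on that target; otherwise the trial is a missed-target candidate
    (``inside_target`` is None) to be adjudicated by the choices module.

    Raises
    ------
    NoStopError
        If speed never falls below ``speed_threshold`` after onset.
    """
    i0 = trace.index_at(onset_ms)
    v = speed(trace)
    slow = np.nonzero(v[i0 + 1:] < speed_threshold)[0]
    if not len(slow):
        raise NoStopError("speed never fell below the stop threshold after onset")
    i = i0 + 1 + int(slow[0])
    pos = trace.xy[i].astype(float)
    inside = None
    for tgt in targets:
        if np.hypot(*(pos - tgt.center)) <= tgt.radius:
            inside = tgt.position_id
            break
    return EndEvent(end_ms=int(trace.t[i]), end_xy=pos,
                    end_speed=float(v[i]), inside_target=inside)


def angle_of(xy: np.ndarray) -> float:
    """Angle of a start-to-point vector in degrees, mapped to [0, 360)."""
    return float(np.degrees(np.arctan2(xy[1], xy[0])) % 360.0)


def angle_at_onset_plus_100(trace: HandTrace, onset_ms: int) -> float:
    """Direction of the hand 100 ms after movement onset.

    The angle (degrees CCW from rightward, in [0, 360)) of the vector from the
    start-point centre to the hand position exactly ten samples after the onset
    sample.

    Raises
    ------
    InsufficientTraceError
        If the trace ends less than 100 ms after onset.
    """
    i0 = trace.index_at(onset_ms)
    i = i0 + 100 // DT_MS
    if i >= len(trace):
        raise InsufficientTraceError("trace ends less than 100 ms after onset")
    return angle_of(trace.xy[i].astype(float))


def compute_rt_mt(onset_ms: float, end_ms: float,
                  target_onset_abs_ms: float) -> tuple[float, float]:
    """Reaction time (target appearance to onset) and movement time (onset to end).

    Anticipatory movements yield a negative RT and are retained; validity
    filtering happens downstream.

    Raises
    ------
    InconsistentEventsError
        If ``end_ms`` is not after ``onset_ms``.
    """
    if end_ms <= onset_ms:
        raise InconsistentEventsError(f"end {end_ms} not after onset {onset_ms}")
    return onset_ms - target_onset_abs_ms, end_ms - onset_ms


@dataclass(frozen=True)
class KinematicSummary:
    """Per-trial kinematic descriptors derived from one hand trace."""

    onset_ms: int
    end_ms: int
    rt_ms: float
    mt_ms: float
    angle_100_deg: float
    end_xy: np.ndarray
    end_speed: float
    inside_target: Optional[PositionId]


def summarize(trace: HandTrace, targets: Sequence[TargetSpec],
              target_onset_abs_ms: float,
              start_radius: float = START_RADIUS_CM,
              speed_threshold: float = SPEED_THRESHOLD_CM_S) -> KinematicSummary:
    """Run onset/end/angle detection on one trace and package the results."""
    onset = detect_onset(trace, start_radius)
    end = detect_end(trace, targets, onset, speed_threshold)
    rt, mt = compute_rt_mt(onset, end.end_ms, target_onset_abs_ms)
    angle = angle_at_onset_plus_100(trace, onset)
    return KinematicSummary(onset_ms=onset, end_ms=end.end_ms, rt_ms=rt, mt_ms=mt,
                            angle_100_deg=angle, end_xy=end.end_xy,
                            end_speed=end.end_speed, inside_target=end.inside_target)
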