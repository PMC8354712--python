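"""Per-trial choice classification, validity filtering, and points accounting.

The initial choice on a trial is read off the hand direction 100 ms after
movement onset: the circle is tiled into four 90-degree quadrants centred on
the target positions, and the occupied quadrant names the chosen target.  2T
trials whose initial direction falls in a quadrant with no displayed target,
and 1T trials whose initial direction is more than 90 degrees from the target,
are excluded.  The final choice is the target the movement ended on; near
misses ending within 4 cm of a target centre are rescued and count as a choice
of that target.  Onsets more than 150 ms from the go cue void the trial and
cost one point; otherwise a rewarded-target hit earns one point, optionally
decayed by 0.2 points per 100 ms of movement time beyond 250 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .design import (POINTS_PER_DOLLAR, POSITION_ANGLE, PositionId,
                     TargetSpec, TrialKind, TrialMeta)
from .errors import InconsistentEventsError, PreconditionError
from .kinematics import KinematicSummary

#: Near-miss rescue: movement ends < 1 cm around a target's edge, i.e. < 4 cm
#: from its centre per the operational figure (the parenthetical 4-cm value is
#: taken as authoritative; with a 1.5-cm radius the two phrasings disagree).
RESCUE_RADIUS_CM = 4.0

QUADRANT_HALF_WIDTH_DEG = 45.0
ONE_TARGET_MAX_DEV_DEG = 90.0
TIMING_WINDOW_MS = 150

#: MT-based reward decay: 0.2 points lost per 100 ms beyond 250 ms.
MT_DECAY_START_MS = 250.0
MT_DECAY_PER_100MS = 0.2


class ExclusionReason(Enum):
    NONE = "none"
    TIMING_WINDOW = "timing_window"
    OFF_QUADRANT_2T = "off_quadrant_2T"
    OFF_TARGET_1T = "off_target_1T"
    NO_CHOICE_MISS = "no_choice_miss"


class PointsMode(Enum):
    RAW = "raw"
    MT_CORRECTED = "mt_corrected"


def circular_distance(a: float, b: float) -> float:
    """Smallest absolute angular distance between two directions, in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def quadrant_of(angle: float) -> PositionId:
    """The target position whose +-45-degree quadrant contains *angle*.

    Quadrants are half-open ``[centre - 45, centre + 45)`` (circularly), so the
    four of them tile [0, 360) exactly.
    """
    angle = float(angle) % 360.0
    for center, pos in ((60, PositionId.POS1), (150, PositionId.POS2),
                        (240, PositionId.POS3), (330, PositionId.POS4)):
        # half-open membership on the circle
        offset = (angle - (center - QUADRANT_HALF_WIDTH_DEG)) % 360.0
        if offset < 2 * QUADRANT_HALF_WIDTH_DEG:
            return pos
    raise AssertionError("quadrants tile the circle")  # pragma: no cover


def check_timing(onset_ms: float, go_ms: float,
                 window_ms: float = TIMING_WINDOW_MS) -> tuple[bool, ExclusionReason]:
    """Valid iff movement onset is within +-150 ms of the go cue (inclusive)."""
    if abs(onset_ms - go_ms) <= window_ms:
        return True, ExclusionReason.NONE
    return False, ExclusionReason.TIMING_WINDOW


def classify_initial_choice(summary: KinematicSummary, meta: TrialMeta
                            ) -> tuple[Optional[PositionId], ExclusionReason]:
    """Initial choice from the 100-ms trajectory angle, with exclusion rules.

    2T: the occupied quadrant must contain a displayed target, else the trial
    is excluded (direction outside both target quadrants).  1T: the angle must
    be within 90 degrees of the target, else excluded; the choice is the
    displayed target (success is still judged on the +-45-degree quadrant).
    """
    angle = summary.angle_100_deg
    if meta.trial_kind is TrialKind.TWO_TARGET:
        pos = quadrant_of(angle)
        if pos in {t.position_id for t in meta.targets}:
            return pos, ExclusionReason.NONE
        return None, ExclusionReason.OFF_QUADRANT_2T
    target = meta.targets[0]
    if circular_distance(angle, target.angle) <= ONE_TARGET_MAX_DEV_DEG:
        return target.position_id, ExclusionReason.NONE
    return None, ExclusionReason.OFF_TARGET_1T


def classify_final_choice(end_xy: np.ndarray, inside_target: Optional[PositionId],
                          targets: Iterable[TargetSpec],
                          rescue_radius: float = RESCUE_RADIUS_CM
                          ) -> tuple[Optional[PositionId], ExclusionReason]:
    """Final choice from the movement endpoint.

    A movement that ended inside a target chose that target.  A missed-target
    trial ending within ``rescue_radius`` of some target centre is rescued and
    counts as a choice of the nearest such target; otherwise the trial carries
    no final choice and is excluded.
    """
    if inside_target is not None:
        return inside_target, ExclusionReason.NONE
    end_xy = np.asarray(end_xy, float)
    dists = [(float(np.hypot(*(end_xy - t.center))), t) for t in targets]
    near = [(d, t) for d, t in dists if d < rescue_radius]
    # targets sit >= 14.1 cm apart, so at most one centre can be within 4 cm
    assert len(near) <= 1, "endpoint within rescue radius of two targets"
    if near:
        return near[0][1].position_id, ExclusionReason.NONE
    return None, ExclusionReason.NO_CHOICE_MISS


def score_points(valid: bool, rewarded_target_hit: bool, mt_ms: float,
                 mode: PointsMode = PointsMode.MT_CORRECTED) -> float:
    """Points for one trial.

    Timing-window violations cost one point; misses and non-rewarded targets
    earn nothing; a rewarded-target hit earns one point, reduced (never below
    zero) by 0.2 points per 100 ms of MT above 250 ms when ``mode`` is
    MT_CORRECTED.  RAW mode drops the MT decay, which isolates choice quality
    from movement speed in the earnings comparison.
    """
    if not valid:
        return -1.0
    if not rewarded_target_hit:
        return 0.0
    if mode is PointsMode.RAW:
        return 1.0
    if mt_ms < 0:
        raise InconsistentEventsError(f"negative MT {mt_ms}")
    decay = MT_DECAY_PER_100MS * max(0.0, mt_ms - MT_DECAY_START_MS) / 100.0
    return max(0.0, 1.0 - decay)


def convert_to_currency(total_points: float) -> float:
    """Convert cumulated points to Canadian dollars (42 points per dollar)."""
    if total_points < 0:
        raise PreconditionError("total points must be non-negative")
    return total_points / POINTS_PER_DOLLAR


@dataclass(frozen=True)
class ChoiceRecord:
    """Validated per-trial outcome: choices, success flags, RT/MT, points."""

    trial_id: int
    valid: bool
    exclusion_reason: ExclusionReason
    initial_choice: Optional[PositionId]
    final_choice: Optional[PositionId]
    success_initial: Optional[bool]
    success_final: Optional[bool]
    rt_ms: Optional[float]
    mt_ms: Optional[float]
    points_raw: float
    points_mt_corrected: float


def evaluate_trial(summary: KinematicSummary, meta: TrialMeta, go_ms: float,
                   rescue_radius: float = RESCUE_RADIUS_CM,
                   timing_window_ms: float = TIMING_WINDOW_MS) -> ChoiceRecord:
    """Full exclusion cascade and scoring for one trial.

    Timing-window violations pre-empt every other label.  Success flags are
    defined only on valid trials with a unique rewarded target, and judge the
    initial direction (final endpoint) against that target's quadrant (target).
    """
    valid, reason = check_timing(summary.onset_ms, go_ms, timing_window_ms)
    initial = final = None
    succ_i = succ_f = None
    rewarded_hit = False
    if valid:
        initial, reason = classify_initial_choice(summary, meta)
        if reason is ExclusionReason.NONE:
            final, reason = classify_final_choice(
                summary.end_xy, summary.inside_target, meta.targets, rescue_radius)
        valid = reason is ExclusionReason.NONE
    if valid:
        # a point is earned by ending on any green target (both are green in
        # rewarded CTRL trials); success flags need a *unique* rewarded target
        rewarded_hit = any(t.rewarded and t.position_id is final for t in meta.targets)
        rewarded = meta.rewarded_target
        if rewarded is not None:
            succ_i = quadrant_of(summary.angle_100_deg) is rewarded.position_id
            succ_f = final is rewarded.position_id
    record = ChoiceRecord(
        trial_id=meta.trial_id, valid=valid, exclusion_reason=reason,
        initial_choice=initial if valid else None,
        final_choice=final if valid else None,
        success_initial=succ_i, success_final=succ_f,
        rt_ms=summary.rt_ms if valid else None,
        mt_ms=summary.mt_ms if valid else None,
        points_raw=score_points(valid, rewarded_hit, summary.mt_ms, PointsMode.RAW),
        points_mt_corrected=score_points(valid, rewarded_hit, summary.mt_ms,
                                         PointsMode.MT_CORRECTED))
    return record


RECORD_COLUMNS = ["subject", "trial_id", "block", "kind", "condition",
                  "configuration", "valid", "exclusion_reason",
                  "initial_choice", "final_choice", "initial_cost_class",
                  "success_initial", "success_final",
                  "rt_ms", "mt_ms", "points_raw", "points_mt_corrected"]


def records_to_frame(records: Iterable[ChoiceRecord], metas: Iterable[TrialMeta],
                     subject: int) -> pd.DataFrame:
    """Tidy per-trial table for one subject (one row per trial)."""
    rows = []
    for rec, meta in zip(records, metas):
        if rec.trial_id != meta.trial_id:
            raise PreconditionError("records and metas must be aligned by trial")
        rows.append({
            "subject": subject, "trial_id": rec.trial_id, "block": meta.block,
            "kind": meta.trial_kind.value, "condition": meta.condition.value,
            "configuration": meta.configuration.value if meta.configuration else "",
            "valid": rec.valid, "exclusion_reason": rec.exclusion_reason.value,
            "initial_choice": rec.initial_choice.name if rec.initial_choice else "",
            "final_choice": rec.final_choice.name if rec.final_choice else "",
            "initial_cost_class": (
                _cost_of(rec.initial_choice) if rec.initial_choice else ""),
            "success_initial": rec.success_initial,
            "success_final": rec.success_final,
            "rt_ms": rec.rt_ms, "mt_ms": rec.mt_ms,
            "points_raw": rec.points_raw,
            "points_mt_corrected": rec.points_mt_corrected,
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _cost_of(pos: PositionId) -> str:
    from .design import classify_cost
    return classify_cost(POSITION_ANGLE[pos]).value


def exclusion_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-reason trial counts (input / excluded-by-reason / analyzed)."""
    counts = frame["exclusion_reason"].value_counts().rename_axis("reason")
    return counts.reset_index(name="n_trials")
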