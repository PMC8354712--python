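"""Task geometry, trial conditions, and pseudo-random schedule generation.

The task is a timed-response reaching experiment: four possible targets sit on a
circle of 10-cm radius around the start point, at 60, 150, 240 and 330 degrees
(counter-clockwise from rightward horizontal).  The 60/240 directions lie on the
major axis of the arm's mobility ellipse and are biomechanically cheap to reach
(low cost, LC); 150/330 lie on the minor axis (high cost, HC).  Two-target (2T)
trials show two targets 90 degrees apart — always one LC and one HC — and reward
(green colour) is assigned congruently (CONG: LC rewarded), incongruently
(INCONG: HC rewarded) or to both/neither (CTRL).  One-target (1T) trials show a
single rewarded or unrewarded target of either cost class.

Movement onset must fall within +-150 ms of a metronome-predicted go cue (the
fourth of four tones 500 ms apart); targets appear 100-400 ms before the go cue,
so the target-to-go interval manipulates the deliberation time available.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidTargetError, PreconditionError, ScheduleInfeasibleError

TARGET_ANGLES = (60, 150, 240, 330)
LC_ANGLES = frozenset({60, 240})
HC_ANGLES = frozenset({150, 330})

TARGET_DISTANCE_CM = 10.0
TARGET_RADIUS_CM = 1.5
START_RADIUS_CM = 0.3

#: 42 cumulated points were exchanged for one Canadian dollar.
POINTS_PER_DOLLAR = 42.0


class PositionId(IntEnum):
    POS1 = 1  # 60 deg, LC
    POS2 = 2  # 150 deg, HC
    POS3 = 3  # 240 deg, LC
    POS4 = 4  # 330 deg, HC


POSITION_ANGLE = {
    PositionId.POS1: 60,
    PositionId.POS2: 150,
    PositionId.POS3: 240,
    PositionId.POS4: 330,
}
ANGLE_POSITION = {v: k for k, v in POSITION_ANGLE.items()}


class CostClass(Enum):
    LC = "LC"
    HC = "HC"


class TrialKind(Enum):
    ONE_TARGET = "1T"
    TWO_TARGET = "2T"


class Condition(Enum):
    CTRL_REWARDED = "CTRL_REWARDED"
    CTRL_UNREWARDED = "CTRL_UNREWARDED"
    CONG = "CONG"
    INCONG = "INCONG"
    R_LC = "R_LC"
    R_HC = "R_HC"
    NR_LC = "NR_LC"
    NR_HC = "NR_HC"


#: Conditions whose success rate is analysed against the rewarded target.
REWARD_CONDITIONS = (Condition.CONG, Condition.INCONG, Condition.R_LC, Condition.R_HC)


class Configuration(Enum):
    CONF1 = "CONF1"  # upward   {60, 150}
    CONF2 = "CONF2"  # leftward {150, 240}
    CONF3 = "CONF3"  # downward {240, 330}
    CONF4 = "CONF4"  # rightward{330, 60}


CONFIG_ANGLES = {
    Configuration.CONF1: (60, 150),
    Configuration.CONF2: (150, 240),
    Configuration.CONF3: (240, 330),
    Configuration.CONF4: (330, 60),
}


def classify_cost(angle: float) -> CostClass:
    """Label a target angle by biomechanical cost class.

    60 and 240 deg lie on the major axis of the mobility ellipse (low cost);
    150 and 330 deg lie on the minor axis (high cost).

    Raises
    ------
    InvalidTargetError
        If *angle* is not one of the four canonical target angles.
    """
    if angle in LC_ANGLES:
        return CostClass.LC
    if angle in HC_ANGLES:
        return CostClass.HC
    raise InvalidTargetError(f"angle {angle!r} is not a task target angle {TARGET_ANGLES}")


@dataclass(frozen=True)
class TargetSpec:
    """One displayed target: canonical angle, reward colour, fixed geometry."""

    angle: int
    rewarded: bool
    distance: float = TARGET_DISTANCE_CM
    radius: float = TARGET_RADIUS_CM

    def __post_init__(self) -> None:
        if self.angle not in TARGET_ANGLES:
            raise InvalidTargetError(f"angle {self.angle!r} not in {TARGET_ANGLES}")

    @property
    def position_id(self) -> PositionId:
        return ANGLE_POSITION[self.angle]

    @property
    def cost_class(self) -> CostClass:
        return classify_cost(self.angle)

    @property
    def center(self) -> np.ndarray:
        """Cartesian target-centre coordinates (cm, start point at origin)."""
        rad = np.deg2rad(self.angle)
        return np.array([self.distance * np.cos(rad), self.distance * np.sin(rad)])


@dataclass(frozen=True)
class TimingConstants:
    tone_interval_ms: int = 500
    hold_before_first_tone_ms: int = 350
    go_window_ms: int = 150
    sample_rate_hz: int = 100

    def __post_init__(self) -> None:
        for name in ("tone_interval_ms", "hold_before_first_tone_ms",
                     "go_window_ms", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise PreconditionError(f"{name} must be strictly positive")

    @property
    def go_ms(self) -> int:
        """Time of the go cue (fourth tone) in ms since the first tone."""
        return 3 * self.tone_interval_ms

    @property
    def dt_ms(self) -> int:
        return 1000 // self.sample_rate_hz


TIMING = TimingConstants()

# Target-onset grid: 100-400 ms before the go cue in 5-ms steps (61 values).
ONSET_GRID_MS = tuple(range(-400, -100 + 1, 5))


@dataclass(frozen=True)
class TrialMeta:
    """Design descriptors of a single trial."""

    trial_id: int
    block: int
    trial_kind: TrialKind
    condition: Condition
    configuration: Optional[Configuration]
    targets: tuple[TargetSpec, ...]
    target_onset_ms: int  # relative to go cue, in [-400, -100], 5-ms steps

    def __post_init__(self) -> None:
        if self.trial_kind is TrialKind.TWO_TARGET:
            if len(self.targets) != 2:
                raise PreconditionError("2T trials need exactly two targets")
            costs = {t.cost_class for t in self.targets}
            if costs != {CostClass.LC, CostClass.HC}:
                raise PreconditionError("2T targets must be one LC and one HC")
        elif len(self.targets) != 1:
            raise PreconditionError("1T trials need exactly one target")
        if self.target_onset_ms % 5 or not -400 <= self.target_onset_ms <= -100:
            raise PreconditionError("target_onset_ms must lie on the -400..-100 5-ms grid")

    @property
    def rewarded_target(self) -> Optional[TargetSpec]:
        """The unique rewarded target, or None when 0 or 2 targets are rewarded."""
        rewarded = [t for t in self.targets if t.rewarded]
        return rewarded[0] if len(rewarded) == 1 else None

    @property
    def target_angles(self) -> tuple[int, ...]:
        return tuple(t.angle for t in self.targets)


# ---------------------------------------------------------------------------
# Trial construction helpers
# ---------------------------------------------------------------------------

def make_two_target(condition: Condition, configuration: Configuration) -> tuple[TargetSpec, TargetSpec]:
    a1, a2 = CONFIG_ANGLES[configuration]
    lc, hc = (a1, a2) if a1 in LC_ANGLES else (a2, a1)
    if condition is Condition.CONG:
        return (TargetSpec(lc, True), TargetSpec(hc, False))
    if condition is Condition.INCONG:
        return (TargetSpec(lc, False), TargetSpec(hc, True))
    if condition is Condition.CTRL_REWARDED:
        return (TargetSpec(lc, True), TargetSpec(hc, True))
    if condition is Condition.CTRL_UNREWARDED:
        return (TargetSpec(lc, False), TargetSpec(hc, False))
    raise PreconditionError(f"{condition} is not a two-target condition")


def one_target_condition(angle: int, rewarded: bool) -> Condition:
    cost = classify_cost(angle)
    if rewarded:
        return Condition.R_LC if cost is CostClass.LC else Condition.R_HC
    return Condition.NR_LC if cost is CostClass.LC else Condition.NR_HC


# ---------------------------------------------------------------------------
# Schedule generation
# ---------------------------------------------------------------------------

_TWO_TARGET_CONDITIONS = (Condition.CONG, Condition.INCONG,
                          Condition.CTRL_REWARDED, Condition.CTRL_UNREWARDED)
# CONG/INCONG each get twice the trials of either CTRL colouring, so that the
# pooled CTRL condition matches CONG and INCONG in size (240/240/240 at n=1200).
_TWO_TARGET_WEIGHT = {Condition.CONG: 1.0, Condition.INCONG: 1.0,
                      Condition.CTRL_REWARDED: 0.5, Condition.CTRL_UNREWARDED: 0.5}

_Cell = tuple  # opaque cell descriptor used during sampling


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Split *total* into integer counts proportional to *weights* (exact sum)."""
    w = np.asarray(weights, dtype=float)
    raw = w / w.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base.tolist()


def _build_cells(n_trials: int, proportions: dict,
                 two_target_conditions: Sequence[Condition]) -> dict:
    p2 = float(proportions["2T"])
    p1 = float(proportions["1T"])
    if abs(p2 + p1 - 1.0) > 1e-9:
        raise PreconditionError("proportions must sum to 1")
    n2 = round(n_trials * p2)
    n1 = n_trials - n2

    cells: dict[_Cell, int] = {}
    if n2:
        keys = [(TrialKind.TWO_TARGET, cond, conf)
                for cond in two_target_conditions for conf in Configuration]
        weights = [_TWO_TARGET_WEIGHT.get(cond, 1.0) for (_, cond, _) in keys]
        for key, count in zip(keys, _largest_remainder(weights, n2)):
            cells[key] = count
    if n1:
        keys = [(TrialKind.ONE_TARGET, angle, rewarded)
                for angle in TARGET_ANGLES for rewarded in (True, False)]
        for key, count in zip(keys, _largest_remainder([1.0] * len(keys), n1)):
            cells[key] = count
    return {k: v for k, v in cells.items() if v > 0}


def _cell_condition(cell: _Cell) -> Condition:
    if cell[0] is TrialKind.TWO_TARGET:
        return cell[1]
    return one_target_condition(cell[1], cell[2])


def _cell_angles(cell: _Cell) -> tuple[int, ...]:
    if cell[0] is TrialKind.TWO_TARGET:
        return CONFIG_ANGLES[cell[2]]
    return (cell[1],)


def build_schedule(n_trials: int = 1200,
                   proportions: Optional[dict] = None,
                   rng_seed: int = 0,
                   two_target_conditions: Sequence[Condition] = _TWO_TARGET_CONDITIONS,
                   n_blocks: int = 6,
                   max_retries: int = 1000) -> list[TrialMeta]:
    """Generate a pseudo-random trial schedule under the task's ordering rules.

    Constraints enforced by construction:

    a. the same condition never occurs on two consecutive trials;
    b. a 2T trial immediately following a 1T trial never includes the 1T
       trial's target;
    c. trial-kind counts match *proportions* exactly (default 60% 2T / 40% 1T),
       with 2T trials balanced across CONG/INCONG/CTRL and configurations and
       1T trials balanced across the four positions and reward colours;
    d. each trial's target onset is drawn uniformly on the 5-ms grid from
       -400 to -100 ms relative to the go cue.

    The order is found by constrained sequential sampling (draw each next trial
    from the cells still allowed given the previous trial); dead ends trigger a
    restart, and ``max_retries`` exhausted restarts raise
    :class:`ScheduleInfeasibleError`.
    """
    if proportions is None:
        proportions = {"2T": 0.6, "1T": 0.4}
    if n_trials % n_blocks:
        raise PreconditionError(f"n_trials={n_trials} not divisible into {n_blocks} blocks")
    rng = np.random.default_rng(rng_seed)
    cells = _build_cells(n_trials, proportions, two_target_conditions)

    for _ in range(max_retries):
        remaining = dict(cells)
        order: list[_Cell] = []
        prev: Optional[_Cell] = None
        ok = True
        while remaining:
            eligible = []
            for cell, count in remaining.items():
                if prev is not None:
                    if _cell_condition(cell) is _cell_condition(prev):
                        continue
                    if (prev[0] is TrialKind.ONE_TARGET
                            and cell[0] is TrialKind.TWO_TARGET
                            and prev[1] in _cell_angles(cell)):
                        continue
                eligible.append((cell, count))
            if not eligible:
                ok = False
                break
            counts = np.array([c for _, c in eligible], dtype=float)
            pick = eligible[rng.choice(len(eligible), p=counts / counts.sum())][0]
            remaining[pick] -= 1
            if not remaining[pick]:
                del remaining[pick]
            order.append(pick)
            prev = pick
        if ok:
            break
    else:
        raise ScheduleInfeasibleError(
            f"no valid ordering found in {max_retries} attempts for {len(cells)} cells")

    block_size = n_trials // n_blocks
    onsets = rng.choice(ONSET_GRID_MS, size=n_trials)
    schedule = []
    for i, cell in enumerate(order):
        kind = cell[0]
        if kind is TrialKind.TWO_TARGET:
            condition, conf = cell[1], cell[2]
            targets = make_two_target(condition, conf)
        else:
            angle, rewarded = cell[1], cell[2]
            condition, conf = one_target_condition(angle, rewarded), None
            targets = (TargetSpec(angle, rewarded),)
        schedule.append(TrialMeta(trial_id=i, block=i // block_size + 1,
                                  trial_kind=kind, condition=condition,
                                  configuration=conf, targets=targets,
                                  target_onset_ms=int(onsets[i])))
    return schedule


def validate_schedule(schedule: Sequence[TrialMeta]) -> None:
    """Brute-force scan of the ordering constraints; raises on any violation."""
    for prev, cur in zip(schedule, schedule[1:]):
        if prev.condition is cur.condition:
            raise ScheduleInfeasibleError(
                f"trials {prev.trial_id}/{cur.trial_id} repeat condition {cur.condition}")
        if (prev.trial_kind is TrialKind.ONE_TARGET
                and cur.trial_kind is TrialKind.TWO_TARGET
                and prev.target_angles[0] in cur.target_angles):
            raise ScheduleInfeasibleError(
                f"trial {cur.trial_id} repeats the 1T target {prev.target_angles[0]}")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

SCHEDULE_COLUMNS = ["trial_id", "block", "kind", "condition", "configuration",
                    "target1_angle", "target1_rewarded",
                    "target2_angle", "target2_rewarded", "target_onset_ms"]


def schedule_to_frame(schedule: Iterable[TrialMeta]) -> pd.DataFrame:
    rows = []
    for m in schedule:
        t1 = m.targets[0]
        t2 = m.targets[1] if len(m.targets) > 1 else None
        rows.append({
            "trial_id": m.trial_id, "block": m.block, "kind": m.trial_kind.value,
            "condition": m.condition.value,
            "configuration": m.configuration.value if m.configuration else "",
            "target1_angle": t1.angle, "target1_rewarded": t1.rewarded,
            "target2_angle": t2.angle if t2 else np.nan,
            "target2_rewarded": t2.rewarded if t2 else np.nan,
            "target_onset_ms": m.target_onset_ms,
        })
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "1.0")
    return bool(value)


def schedule_from_frame(frame: pd.DataFrame) -> list[TrialMeta]:
    schedule = []
    for row in frame.itertuples(index=False):
        kind = TrialKind(row.kind)
        targets = [TargetSpec(int(float(row.target1_angle)), _as_bool(row.target1_rewarded))]
        if kind is TrialKind.TWO_TARGET:
            targets.append(TargetSpec(int(float(row.target2_angle)),
                                      _as_bool(row.target2_rewarded)))
        schedule.append(TrialMeta(
            trial_id=int(row.trial_id), block=int(row.block), trial_kind=kind,
            condition=Condition(row.condition),
            configuration=Configuration(row.configuration) if row.configuration else None,
            targets=tuple(targets), target_onset_ms=int(row.target_onset_ms)))
    return schedule
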