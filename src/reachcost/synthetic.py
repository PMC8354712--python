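"""Synthetic cohort generator: a seeded forward model of the reaching task.

Each simulated subject runs a full pseudo-random session (default 1,200
trials).  Movement onset follows the timed-response design: participants aim
for the go cue (gaussian jitter around the fourth tone) but cannot initiate
before the target has been processed for a per-trial processing floor (~200
ms), which concentrates reaction times above 200 ms and caps RT at ~250 ms for
the latest-appearing targets, as the task's timing implies.  The probability
that the initial movement direction lies in the rewarded target's quadrant is
a per-condition, per-RT-bin curve; the default calibration encodes the
published bin-level success rates so that running the full analysis pipeline
on a default cohort is a round-trip correctness check.  Between-subject
heterogeneity is a shared probability-scale ability offset per subject,
stratified over the cohort (subjects sit at the mid-quantiles of a gaussian
ability distribution); cell centres are solved against the cohort's offset
set so the cohort-mean probability of every cell equals the configured curve
exactly despite clipping at the probability bounds.

Hand traces are minimum-jerk paths toward the initially chosen direction, with
optional mid-flight redirection (change of mind) so final-choice success
exceeds initial-choice success by a configured number of percentage points,
and a configurable fraction of trials stopping just outside the target (near
misses inside or beyond the 4-cm rescue zone).  The movement profile is
time-shifted so that the start-circle crossing — what onset detection measures
— lands on the drawn onset sample, keeping generative and measured RT aligned.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import __version__
from .design import (START_RADIUS_CM, TARGET_DISTANCE_CM, Condition,
                     Configuration, CostClass, TimingConstants, TrialKind,
                     TrialMeta, build_schedule, schedule_to_frame,
                     schedule_from_frame)
from .errors import PreconditionError
from .kinematics import DT_MS, HandTrace

N_BINS = 13


def subject_offsets(n_subjects: int, sigma: float) -> np.ndarray:
    """Stratified subject-ability offsets: sigma times the normal mid-quantiles.

    Subjects form a representative (quantile-stratified) sample of a gaussian
    ability distribution rather than an iid draw, so the cohort-mean success
    of every cell stays pinned to the configured curve while the
    between-subject spread — hence the width of group confidence intervals —
    is still governed by ``sigma``.  Subjects are exchangeable; the offset is
    tied to the subject index.
    """
    if sigma == 0 or n_subjects == 1:
        return np.zeros(n_subjects)
    q = (np.arange(n_subjects) + 0.5) / n_subjects
    return sigma * np.asarray(special.ndtri(q))


def solve_cell_center(p: float, offsets: np.ndarray) -> float:
    """Cell centre m such that mean_i clip(m + offsets_i, 0, 1) equals p exactly.

    High cells clip at 1, so the centre sits above the target mean; solving
    against the cohort's actual offset set makes every configured cell mean
    exact by construction (the round-trip consistency the generator promises).
    """
    p = float(p)
    if p in (0.0, 1.0) or not np.any(offsets):
        return p

    def gap(m: float) -> float:
        return float(np.mean(np.clip(m + offsets, 0.0, 1.0))) - p

    return float(optimize.brentq(gap, -4.0, 5.0))


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic cohort.

    ``success_curve`` maps condition names (CONG/INCONG/R_LC/R_HC, also used
    for the unrewarded 1T conditions of matching cost class) to 13 per-RT-bin
    probabilities that the initial direction lands in the rewarded (or, for 1T,
    displayed) target's quadrant.  ``ctrl_lc_preference`` gives the per-
    configuration probability of initially heading to the LC target on CTRL
    trials.  ``subject_effect_sd`` is the between-subject SD of a shared
    probability-scale ability offset added to every cell probability
    (clipped to [0, 1] with a mean-preserving cell centre; subjects sit at
    stratified quantiles of the offset distribution).
    """

    n_subjects: int = 22
    n_trials: int = 1200
    base_seed: int = 2021
    seeds: Optional[list[int]] = None
    success_curve: dict = field(default_factory=dict)
    ctrl_lc_preference: dict = field(default_factory=dict)
    change_of_mind_gain: float = 2.6       # percentage points, initial -> final
    miss_rate: float = 0.09                # fraction of trials stopping off-target
    miss_rescue_fraction: float = 0.8      # misses landing inside the 4-cm zone
    onset_jitter_sd_ms: float = 50.0       # SD of go-cue synchronization error
    rt_floor_mean_ms: float = 205.0        # per-trial target-processing floor
    rt_floor_sd_ms: float = 15.0
    mt_mean_ms: dict = field(default_factory=lambda: {"LC": 280.0, "HC": 330.0})
    mt_sd_ms: float = 40.0
    mt_min_ms: float = 150.0
    angular_noise_sd_deg: float = 8.0      # jitter of the initial direction
    endpoint_scatter_cm: float = 0.3       # scatter of hit endpoints in-target
    subject_effect_sd: float = 0.12        # probability-scale between-subject SD
    timing: TimingConstants = field(default_factory=TimingConstants)

    def __post_init__(self) -> None:
        for cond, curve in self.success_curve.items():
            curve = np.asarray(curve, float)
            if curve.shape != (N_BINS,) or np.any((curve < 0) | (curve > 1)):
                raise PreconditionError(f"curve for {cond} must be 13 probabilities")
            self.success_curve[cond] = curve
        if not 0 <= self.miss_rate < 1:
            raise PreconditionError("miss_rate must be in [0, 1)")
        for p in self.ctrl_lc_preference.values():
            if not 0 <= p <= 1:
                raise PreconditionError("ctrl_lc_preference must be probabilities")
        if min(self.mt_mean_ms.values()) <= 0:
            raise PreconditionError("MT means must be positive")
        if self.mt_mean_ms["LC"] >= self.mt_mean_ms["HC"]:
            raise PreconditionError("LC movements must be faster than HC on average")

    def subject_seeds(self) -> list[int]:
        if self.seeds is not None:
            seeds = [int(s) for s in self.seeds]
        else:
            state = np.random.SeedSequence(self.base_seed).generate_state(self.n_subjects)
            seeds = [int(s % (2 ** 31)) for s in state]
        if len(seeds) != self.n_subjects:
            raise PreconditionError("need one seed per subject")
        if len(set(seeds)) != len(seeds):
            raise PreconditionError("seed collision across subjects")
        return seeds

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["success_curve"] = {k: np.asarray(v).tolist()
                              for k, v in self.success_curve.items()}
        d["timing"] = dataclasses.asdict(self.timing)
        return d


# Published bin-level quantities encoded by the default calibration (all in
# success-rate percent): first-bin CONG mean 94.4; CONG-INCONG differences of
# 41.5/32.2/22.5/18.8/13.5/10.9/10.5 points over bins 1-7; INCONG 91.4 in bin
# 8 ([340,360) ms); INCONG-vs-R-HC differences 32.3/36.3/24.2/19.9/14.7/12.2/
# 11.6 over bins 1-7; a 2.6-point initial-to-final gain; ~9% missed targets.
_CONG_INCONG_DIFF = np.array([41.5, 32.2, 22.5, 18.8, 13.5, 10.9, 10.5]) / 100.0
_INCONG_RHC_DIFF = np.array([32.3, 36.3, 24.2, 19.9, 14.7, 12.2, 11.6]) / 100.0


def default_calibration(**overrides) -> GeneratorConfig:
    """The calibrated study-condition configuration.

    The CONG curve starts at 0.944 and plateaus at 0.955; INCONG follows CONG
    minus the published bin-wise differences through bin 7, hits 0.914 in bin
    8 and relaxes linearly to 0.95; the 1T curves mirror the published
    INCONG-vs-R-HC differences (R-LC is indistinguishable from CONG).
    """
    cong = np.full(N_BINS, 0.955)
    cong[0] = 0.944
    incong = np.empty(N_BINS)
    incong[:7] = cong[:7] - _CONG_INCONG_DIFF
    incong[7] = 0.914
    incong[8:] = np.linspace(0.914, 0.95, 6)[1:]
    r_lc = cong.copy()
    r_hc = r_lc.copy()
    r_hc[:7] = np.minimum(1.0, incong[:7] + _INCONG_RHC_DIFF)
    curves = {"CONG": cong, "INCONG": incong, "R_LC": r_lc, "R_HC": r_hc}
    prefs = {c.value: 0.75 for c in Configuration}
    kwargs = dict(success_curve=curves, ctrl_lc_preference=prefs)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def null_calibration(**overrides) -> GeneratorConfig:
    """A zero-bias cohort: every choice probability at chance, no misses."""
    curves = {k: np.full(N_BINS, 0.5) for k in ("CONG", "INCONG", "R_LC", "R_HC")}
    prefs = {c.value: 0.5 for c in Configuration}
    kwargs = dict(success_curve=curves, ctrl_lc_preference=prefs,
                  change_of_mind_gain=0.0, miss_rate=0.0, subject_effect_sd=0.0)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@dataclass
class SubjectData:
    subject: int
    seed: int
    schedule: list[TrialMeta]
    traces: list[HandTrace]


@dataclass
class CohortData:
    config: GeneratorConfig
    subjects: list[SubjectData]


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------

def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 3 * u ** 2 - 2 * u ** 3


# fraction of movement duration at which a 10-cm min-jerk reach crosses the
# 0.3-cm start circle (s(tau) = 0.03)
_TAU_CROSS = float(optimize.brentq(lambda t: _min_jerk(np.array([t]))[0]
                                   - START_RADIUS_CM / TARGET_DISTANCE_CM, 1e-6, 0.5))


def synth_trace(rng: np.random.Generator, onset_ms: int, target_onset_abs_ms: float,
                initial_angle_deg: float, endpoint_xy: np.ndarray, mt_ms: float,
                redirect: bool, hold_noise_cm: float = 0.02) -> HandTrace:
    """One minimum-jerk trial trace.

    The trace starts ~100 ms before target onset, holds at the start point
    until movement, crosses the start circle on the ``onset_ms`` sample, and
    (when ``redirect``) bends from the initial direction to the endpoint late
    enough that the 100-ms direction probe still sees the initial choice.
    """
    t_start = int(np.floor((target_onset_abs_ms - 100) / DT_MS) * DT_MS)
    # shift by 2 ms so the start-circle crossing strictly precedes the onset
    # sample's position check (r > 0.3 exactly at tau_cross would round down)
    move_t0 = onset_ms - _TAU_CROSS * mt_ms - 2.0
    t_end = int(np.ceil((move_t0 + mt_ms) / DT_MS) * DT_MS) + 6 * DT_MS
    t = np.arange(t_start, t_end + DT_MS, DT_MS)

    tau = np.clip((t - move_t0) / mt_ms, 0.0, 1.0)
    s = _min_jerk(tau)
    rad = np.deg2rad(initial_angle_deg)
    u_init = np.array([np.cos(rad), np.sin(rad)])
    path_a = np.outer(s, TARGET_DISTANCE_CM * u_init)
    path_b = np.outer(s, endpoint_xy)
    if redirect:
        tau_sw = min(0.97, max(0.55, _TAU_CROSS + (100 + 2 * DT_MS) / mt_ms))
        w = _smoothstep((tau - tau_sw) / (1.0 - tau_sw))
    else:
        w = _smoothstep(tau)  # smooth early handover: both paths nearly equal
    xy = (1 - w)[:, None] * path_a + w[:, None] * path_b

    pre = tau <= 0
    xy[pre] = rng.normal(0.0, hold_noise_cm, size=(int(pre.sum()), 2))
    post = tau >= 1
    xy[post] = endpoint_xy
    return HandTrace(t=t, x=xy[:, 0], y=xy[:, 1])


# ---------------------------------------------------------------------------
# Subject / cohort simulation
# ---------------------------------------------------------------------------

def _population_structure(config: GeneratorConfig) -> dict:
    """Stratified subject offsets plus per-cell centres with exact cohort means."""
    offsets = subject_offsets(config.n_subjects, config.subject_effect_sd)
    table: dict = {"offsets": offsets}
    for cond, curve in config.success_curve.items():
        table[cond] = np.array([solve_cell_center(p, offsets) for p in curve])
    for conf, p in config.ctrl_lc_preference.items():
        table[("ctrl", conf)] = solve_cell_center(p, offsets)
    return table


def _curve_key(condition: Condition) -> str:
    if condition in (Condition.CONG, Condition.INCONG):
        return condition.value
    # 1T conditions share the direction-accuracy curve of their cost class
    if condition in (Condition.R_LC, Condition.NR_LC):
        return "R_LC"
    return "R_HC"


def _subject_prob(center: float, offset: float, base_p: float) -> float:
    if base_p in (0.0, 1.0):
        return float(base_p)
    return float(np.clip(center + offset, 0.0, 1.0))


def simulate_subject(config: GeneratorConfig, subject_index: int,
                     structure: Optional[dict] = None) -> SubjectData:
    """Simulate one full session (schedule + traces) for one subject."""
    seed = config.subject_seeds()[subject_index]
    rng = np.random.default_rng(seed)
    if structure is None:
        structure = _population_structure(config)
    intercepts = structure
    schedule = build_schedule(config.n_trials,
                              rng_seed=int(rng.integers(2 ** 31)))
    offset = float(structure["offsets"][subject_index])
    go = config.timing.go_ms
    edges = 200.0 + 20.0 * np.arange(N_BINS + 1)
    gain = config.change_of_mind_gain / 100.0

    traces = []
    for meta in schedule:
        t_on = go + meta.target_onset_ms
        floor = max(0.0, rng.normal(config.rt_floor_mean_ms, config.rt_floor_sd_ms))
        onset = max(go + rng.normal(0.0, config.onset_jitter_sd_ms), t_on + floor)
        onset = int(round(onset / DT_MS) * DT_MS)
        rt = onset - t_on
        b = int(np.clip(np.searchsorted(edges, rt, side="right") - 1, 0, N_BINS - 1))

        redirect = False
        if meta.condition in (Condition.CTRL_REWARDED, Condition.CTRL_UNREWARDED):
            conf = meta.configuration.value
            p_lc = _subject_prob(intercepts[("ctrl", conf)], offset,
                                 config.ctrl_lc_preference[conf])
            lc = next(tg for tg in meta.targets if tg.cost_class is CostClass.LC)
            hc = next(tg for tg in meta.targets if tg.cost_class is CostClass.HC)
            initial_target = lc if rng.random() < p_lc else hc
            final_target = initial_target
            initial_angle = initial_target.angle
        else:
            key = _curve_key(meta.condition)
            base_p = float(config.success_curve[key][b])
            p = _subject_prob(intercepts[key][b], offset, base_p)
            success = rng.random() < p
            if meta.trial_kind is TrialKind.TWO_TARGET:
                ref = meta.rewarded_target
                other = next(tg for tg in meta.targets if tg is not ref)
                initial_target = ref if success else other
                final_target = initial_target
                if not success and gain > 0:
                    # corrective change of mind.  The redirect probability is
                    # scaled by the *population* failure rate, so the group
                    # mean of final-choice success exceeds initial-choice
                    # success by exactly the configured gain: q*(1-E[p]) = gain
                    if rng.random() < min(1.0, gain / max(1e-12, 1.0 - base_p)):
                        final_target = ref
                        redirect = True
                initial_angle = initial_target.angle + rng.normal(
                    0.0, config.angular_noise_sd_deg)
            else:
                target = meta.targets[0]
                final_target = target
                if success:
                    initial_angle = target.angle + rng.normal(
                        0.0, config.angular_noise_sd_deg)
                else:
                    # deviated start: outside the target quadrant but within
                    # the 90-degree keep window of 1T trials
                    dev = rng.uniform(50.0, 88.0) * rng.choice([-1.0, 1.0])
                    initial_angle = target.angle + dev
                    redirect = True

        mt = max(config.mt_min_ms,
                 rng.normal(config.mt_mean_ms[final_target.cost_class.value],
                            config.mt_sd_ms))
        center = final_target.center
        if rng.random() < config.miss_rate:
            direction = rng.uniform(0.0, 2 * np.pi)
            if rng.random() < config.miss_rescue_fraction:
                dist = rng.uniform(2.0, 3.5)   # inside the 4-cm rescue zone
            else:
                dist = rng.uniform(4.5, 6.0)   # a clear miss
            endpoint = center + dist * np.array([np.cos(direction), np.sin(direction)])
        else:
            scatter = rng.normal(0.0, config.endpoint_scatter_cm, size=2)
            norm = np.hypot(*scatter)
            limit = 0.8 * final_target.radius
            if norm > limit:
                scatter *= limit / norm
            endpoint = center + scatter
        traces.append(synth_trace(rng, onset, t_on, initial_angle, endpoint,
                                  mt, redirect))
    return SubjectData(subject=subject_index, seed=seed,
                       schedule=schedule, traces=traces)


def simulate_cohort(config: GeneratorConfig) -> CohortData:
    """Simulate all subjects independently (per-subject seeds, no shared state)."""
    config.subject_seeds()  # validates uniqueness up front
    structure = _population_structure(config)
    subjects = [simulate_subject(config, i, structure)
                for i in range(config.n_subjects)]
    return CohortData(config=config, subjects=subjects)


# ---------------------------------------------------------------------------
# Dataset directory I/O
# ---------------------------------------------------------------------------

def write_dataset(cohort: CohortData, path: Path) -> None:
    """Write a cohort as a dataset directory: trials.csv, traces.csv, manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trial_frames = []
    trace_frames = []
    for sub in cohort.subjects:
        sf = schedule_to_frame(sub.schedule)
        sf.insert(0, "subject", sub.subject)
        trial_frames.append(sf)
        for meta, trace in zip(sub.schedule, sub.traces):
            trace_frames.append(pd.DataFrame({
                "subject": sub.subject, "trial_id": meta.trial_id,
                "t_ms": trace.t, "x_cm": np.round(trace.x, 5),
                "y_cm": np.round(trace.y, 5)}))
    pd.concat(trial_frames).to_csv(path / "trials.csv", index=False)
    pd.concat(trace_frames).to_csv(path / "traces.csv", index=False)
    manifest = {"package": "reachcost", "version": __version__,
                "seeds": [s.seed for s in cohort.subjects],
                "config": cohort.config.to_dict()}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(path: Path) -> CohortData:
    """Load a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["timing"] = TimingConstants(**cfg_dict["timing"])
    config = GeneratorConfig(**cfg_dict)
    trials = pd.read_csv(path / "trials.csv", keep_default_na=False)
    traces = pd.read_csv(path / "traces.csv")
    subjects = []
    for subject, strials in trials.groupby("subject", sort=True):
        schedule = schedule_from_frame(strials.drop(columns="subject"))
        straces = traces[traces.subject == subject]
        tr_list = []
        for meta in schedule:
            tt = straces[straces.trial_id == meta.trial_id]
            tr_list.append(HandTrace(t=tt["t_ms"].to_numpy(),
                                     x=tt["x_cm"].to_numpy(),
                                     y=tt["y_cm"].to_numpy()))
        subjects.append(SubjectData(subject=int(subject),
                                    seed=manifest["seeds"][len(subjects)],
                                    schedule=schedule, traces=tr_list))
    return CohortData(config=config, subjects=subjects)
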