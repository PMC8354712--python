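"""Kinematic event detection against brute-force per-sample oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachcost.design import TargetSpec
from reachcost.errors import (InconsistentEventsError, InsufficientTraceError,
                              NoMovementError, NoStopError, PreconditionError)
from reachcost.kinematics import (HandTrace, angle_at_onset_plus_100,
                                  compute_rt_mt, detect_end, detect_onset,
                                  speed, summarize)

from conftest import make_trace


def random_trace(rng, n=60, scale=2.0):
    """A random walk starting at the origin (inside the start circle)."""
    steps = rng.normal(0, scale / 10, size=(n, 2))
    xy = np.cumsum(np.vstack([[0.0, 0.0], steps]), axis=0)
    return make_trace(xy)


class TestOnset:
    def test_first_excursion(self):
        xy = [(0, 0)] * 35 + [(0.5, 0.0)] * 5
        assert detect_onset(make_trace(xy)) == 350

    def test_matches_per_sample_scan(self, rng):
        """Oracle equivalence: exhaustive scan of the first outside sample."""
        checked = 0
        for _ in range(200):
            trace = random_trace(rng)
            r = np.hypot(trace.x, trace.y)
            outside = [i for i in range(len(trace)) if r[i] > 0.3]
            if not outside:
                with pytest.raises(NoMovementError):
                    detect_onset(trace)
            else:
                assert detect_onset(trace) == trace.t[outside[0]]
                checked += 1
        assert checked > 100

    def test_never_leaving_start(self):
        with pytest.raises(NoMovementError):
            detect_onset(make_trace([(0.0, 0.0)] * 30))

    def test_starting_outside_is_precondition_violation(self):
        with pytest.raises(PreconditionError):
            detect_onset(make_trace([(5.0, 0.0)] * 10))


class TestEnd:
    def test_stop_inside_target(self, straight_reach):
        trace, target = straight_reach
        onset = detect_onset(trace)
        end = detect_end(trace, [target], onset)
        assert end.inside_target is target.position_id
        assert np.hypot(*(end.end_xy - target.center)) <= target.radius

    def test_stop_far_from_target_is_miss_candidate(self):
        """Decelerating to rest 3 cm from the centre of a 1.5-cm target."""
        target = TargetSpec(60, True)
        stop = 0.7 * target.center  # 7 cm out -> 3 cm from centre
        xy = [(0, 0)] * 5 + [tuple(s * stop) for s in np.linspace(0, 1, 10)[1:]] \
            + [tuple(stop)] * 5
        trace = make_trace(xy)
        end = detect_end(trace, [target], detect_onset(trace))
        assert end.inside_target is None

    def test_stop_one_cm_from_centre_is_hit(self):
        target = TargetSpec(240, False)
        stop = 0.9 * target.center  # 1 cm inside the target edge
        xy = [(0, 0)] * 5 + [tuple(s * stop) for s in np.linspace(0, 1, 10)[1:]] \
            + [tuple(stop)] * 5
        trace = make_trace(xy)
        assert detect_end(trace, [target], detect_onset(trace)).inside_target \
            is target.position_id

    def test_zero_threshold_never_stops(self, straight_reach, rng):
        trace, target = straight_reach
        noisy = HandTrace(t=trace.t, x=trace.x + rng.normal(0, 1e-3, len(trace)),
                          y=trace.y + rng.normal(0, 1e-3, len(trace)))
        with pytest.raises(NoStopError):
            detect_end(noisy, [target], detect_onset(noisy), speed_threshold=0.0)

    def test_matches_per_sample_scan(self, rng):
        """Oracle: first post-onset sample whose central-difference speed is slow."""
        target = TargetSpec(60, True)
        for _ in range(100):
            trace = random_trace(rng, n=40, scale=8.0)
            try:
                onset = detect_onset(trace)
            except NoMovementError:
                continue
            v = speed(trace)
            i0 = int(np.where(trace.t == onset)[0][0])
            slow = [i for i in range(i0 + 1, len(trace)) if v[i] < 5.0]
            if not slow:
                with pytest.raises(NoStopError):
                    detect_end(trace, [target], onset, speed_threshold=5.0)
            else:
                end = detect_end(trace, [target], onset, speed_threshold=5.0)
                assert end.end_ms == trace.t[slow[0]]


class TestAngle:
    @pytest.mark.parametrize("angle", [0, 60, 90, 150, 240, 330])
    def test_straight_line_angle(self, angle):
        rad = np.deg2rad(angle)
        u = np.array([np.cos(rad), np.sin(rad)])
        xy = [(0, 0)] * 3 + [tuple(s * 10 * u) for s in np.linspace(0.05, 1, 15)]
        trace = make_trace(xy)
        onset = detect_onset(trace)
        assert angle_at_onset_plus_100(trace, onset) == pytest.approx(angle % 360)

    def test_position_up_is_90_degrees(self):
        xy = [(0, 0)] * 2 + [(0.0, 0.4)] + [(0.0, 1.0)] * 12
        trace = make_trace(xy)
        assert angle_at_onset_plus_100(trace, 20) == pytest.approx(90.0)

    def test_short_trace_raises(self):
        xy = [(0, 0)] * 2 + [(1.0, 0.0)] * 5  # only 50 ms past onset
        with pytest.raises(InsufficientTraceError):
            angle_at_onset_plus_100(make_trace(xy), 20)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(phi=st.floats(0, 360), seed=st.integers(0, 10 ** 6))
    def test_rotation_equivariance(self, phi, seed):
        """Rotating a trace by phi rotates the 100-ms angle by phi (mod 360)."""
        rng = np.random.default_rng(seed)
        # outward steps with a floor so onset is early and 100 ms of trace remain
        steps = np.abs(rng.normal(0.3, 0.2, size=(16, 2))) + 0.1
        xy = np.vstack([np.zeros((3, 2)), np.cumsum(steps, axis=0)])
        trace = make_trace(xy)
        rad = np.deg2rad(phi)
        rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        rotated = make_trace(xy @ rot.T)
        onset = detect_onset(trace)
        assert detect_onset(rotated) == onset
        a = angle_at_onset_plus_100(trace, onset)
        b = angle_at_onset_plus_100(rotated, onset)
        assert ((b - a - phi + 180) % 360 - 180) == pytest.approx(0, abs=1e-6)


class TestRtMt:
    @pytest.mark.parametrize("onset,end,target_on,rt,mt", [
        (1550, 1850, 1200, 350, 300),   # target 300 ms before go, onset 50 after
        (1400, 1700, 1400, 0, 300),     # movement right at target appearance
        (1650, 1950, 1400, 250, 300),   # latest target, latest allowed onset
    ])
    def test_arithmetic(self, onset, end, target_on, rt, mt):
        assert compute_rt_mt(onset, end, target_on) == (rt, mt)

    def test_end_before_onset_raises(self):
        with pytest.raises(InconsistentEventsError):
            compute_rt_mt(500, 400, 100)

    def test_conservation(self, straight_reach):
        """rt + mt always equals end minus target onset."""
        trace, target = straight_reach
        summary = summarize(trace, [target], target_onset_abs_ms=100)
        assert summary.rt_ms + summary.mt_ms == summary.end_ms - 100
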