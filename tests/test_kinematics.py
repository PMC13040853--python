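"""Angle computation, event detection, quality grading, holds, speed."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exengage.errors import (
    ConfigurationError,
    MissingDataError,
    ModeError,
    UnsupportedExerciseError,
)
from exengage.kinematics import (
    JOINT_INDEX,
    JOINT_NAMES,
    ExerciseDefinition,
    SkeletonSequence,
    assess_quality,
    default_exercises,
    detect_attempts,
    joint_angle,
    speed_warnings,
    time_hold,
    trunk_lean,
)
from exengage.synthetic_data import (
    DEFAULT_GEOMETRY,
    MotionProfile,
    _neutral_pose,
    simulate_skeleton,
)


def static_sequence(pose: np.ndarray, n_frames: int = 60) -> SkeletonSequence:
    times = np.arange(n_frames) / 30.0
    xyz = np.repeat(pose[None], n_frames, axis=0)
    return SkeletonSequence(times=times, xyz=xyz)


@pytest.fixture
def neutral_seq():
    return static_sequence(_neutral_pose(DEFAULT_GEOMETRY))


class TestJointAngles:
    def test_standing_straight_gives_zero_flexion(self, neutral_seq):
        assert joint_angle(neutral_seq, 0, "hip_flexion_l") == pytest.approx(0.0, abs=1e-9)
        assert joint_angle(neutral_seq, 0, "knee_flexion_r") == pytest.approx(0.0, abs=1e-9)

    def test_thigh_perpendicular_to_trunk_is_90_degrees(self, neutral_seq):
        pose = neutral_seq.xyz[0].copy()
        hip = pose[JOINT_INDEX["hip_l"]]
        pose[JOINT_INDEX["knee_l"]] = hip + np.array([0.0, 0.0, 0.40])
        seq = static_sequence(pose)
        assert joint_angle(seq, 0, "hip_flexion_l") == pytest.approx(90.0, abs=1e-9)

    def test_angle_matches_arccos_oracle_on_arbitrary_coordinates(self, rng, neutral_seq):
        """Hip flexion equals 180 deg minus a hand dot-product angle."""
        for _ in range(25):
            pose = neutral_seq.xyz[0].copy()
            pose[JOINT_INDEX["knee_l"]] = pose[JOINT_INDEX["hip_l"]] + rng.normal(0, 0.3, 3)
            seq = static_sequence(pose)
            trunk = pose[JOINT_INDEX["spine_shoulder"]] - pose[JOINT_INDEX["spine_base"]]
            thigh = pose[JOINT_INDEX["knee_l"]] - pose[JOINT_INDEX["hip_l"]]
            cos = trunk @ thigh / (np.linalg.norm(trunk) * np.linalg.norm(thigh))
            expected = 180.0 - np.degrees(np.arccos(np.clip(cos, -1, 1)))
            assert joint_angle(seq, 0, "hip_flexion_l") == pytest.approx(expected, abs=1e-9)

    def test_missing_marker_raises_with_frame_and_marker(self, neutral_seq):
        seq = static_sequence(neutral_seq.xyz[0])
        seq.missing[3, JOINT_INDEX["knee_l"]] = True
        with pytest.raises(MissingDataError, match="frame 3.*knee_l"):
            joint_angle(seq, 3, "hip_flexion_l")


class TestTrunkLean:
    def test_upright_spine_is_zero(self, neutral_seq):
        assert trunk_lean(neutral_seq, 0) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("tilt_deg", [5.0, 15.0, 40.0])
    def test_lateral_tilt_recovered_exactly(self, tilt_deg, neutral_seq):
        """Rotating the spine in the frontal plane reads back the rotation."""
        pose = neutral_seq.xyz[0].copy()
        base = pose[JOINT_INDEX["spine_base"]]
        v = pose[JOINT_INDEX["spine_shoulder"]] - base
        a = np.radians(tilt_deg)
        rot = np.array([v[0] * np.cos(a) - v[1] * np.sin(a),
                        v[0] * np.sin(a) + v[1] * np.cos(a), v[2]])
        pose[JOINT_INDEX["spine_shoulder"]] = base + rot
        assert trunk_lean(static_sequence(pose), 0) == pytest.approx(tilt_deg, abs=1e-9)

    def test_pure_sagittal_tilt_reads_zero(self, neutral_seq):
        pose = neutral_seq.xyz[0].copy()
        pose[JOINT_INDEX["spine_shoulder"]][2] += 0.2  # forward only
        assert trunk_lean(static_sequence(pose), 0) == pytest.approx(0.0, abs=1e-9)


class TestDetectAttempts:
    def test_noiseless_excursions_counted_exactly(self):
        prof = MotionProfile("hip_flexion", n_reps=3, peak_angle=45.0, seed=0)
        events = detect_attempts(simulate_skeleton(prof), "hip_flexion")
        assert len(events) == 3
        assert all(e.start_time < e.peak_time < e.end_time for e in events)
        assert [e.start_time for e in events] == sorted(e.start_time for e in events)

    def test_constant_posture_yields_no_attempts(self):
        prof = MotionProfile("hip_flexion", n_reps=0, seed=0)
        assert detect_attempts(simulate_skeleton(prof), "hip_flexion") == []

    def test_subthreshold_peak_yields_no_attempts(self):
        """Excursions peaking at 19.5 deg never satisfy the 20 deg rule."""
        prof = MotionProfile("hip_flexion", n_reps=3, peak_angle=19.5, seed=0)
        assert detect_attempts(simulate_skeleton(prof), "hip_flexion") == []

    def test_unknown_exercise_rejected(self):
        prof = MotionProfile("hip_flexion", n_reps=1, seed=0)
        with pytest.raises(UnsupportedExerciseError):
            detect_attempts(simulate_skeleton(prof), "jumping_jack")

    def test_bilateral_reps_alternate_sides(self):
        prof = MotionProfile("hip_flexion", n_reps=4, seed=0)
        events = detect_attempts(simulate_skeleton(prof), "hip_flexion")
        assert [e.side for e in events] == ["l", "r", "l", "r"]

    def test_attempt_monotone_in_threshold(self):
        """Raising any attempt threshold never increases the count."""
        prof = MotionProfile("hip_flexion", n_reps=4, peak_angle=45.0,
                             noise_sd=0.005, seed=3)
        seq = simulate_skeleton(prof)
        counts = []
        for thr in (10.0, 20.0, 40.0, 60.0):
            ex = ExerciseDefinition("hip_flexion", laterality="bilateral",
                                    attempt_rules={"hip_flexion_deg": thr})
            counts.append(len(detect_attempts(seq, ex)))
        assert counts == sorted(counts, reverse=True)

    def test_small_dropout_rate_does_not_change_counts(self):
        for name in ("hip_flexion", "squat", "kick"):
            clean = MotionProfile(name, n_reps=4, seed=11)
            dropped = MotionProfile(name, n_reps=4, dropout_rate=0.05, seed=11)
            n0 = len(detect_attempts(simulate_skeleton(clean), name))
            n1 = len(detect_attempts(simulate_skeleton(dropped), name))
            assert n0 == n1 == 4


class TestAssessQuality:
    def test_deep_upright_squat_is_high_quality(self):
        prof = MotionProfile("squat", n_reps=3, seed=2)  # 90 deg, no lean
        seq = simulate_skeleton(prof)
        ex = default_exercises()["squat"]
        graded = [assess_quality(e, seq, ex) for e in detect_attempts(seq, ex)]
        assert all(g.quality for g in graded)
        assert all(g.failed_criteria == [] for g in graded)

    def test_shallow_squat_fails_depth_rule(self):
        prof = MotionProfile("squat", n_reps=2, peak_angle=55.0, seed=2)
        seq = simulate_skeleton(prof)
        ex = default_exercises()["squat"]
        graded = [assess_quality(e, seq, ex) for e in detect_attempts(seq, ex)]
        assert all(not g.quality for g in graded)
        assert all("hip_depth" in g.failed_criteria for g in graded)

    def test_leaning_squat_fails_trunk_rule(self):
        prof = MotionProfile("squat", n_reps=2, seed=2,
                             params={"trunk_lean_deg": 15.0})
        seq = simulate_skeleton(prof)
        ex = default_exercises()["squat"]
        graded = [assess_quality(e, seq, ex) for e in detect_attempts(seq, ex)]
        assert all("trunk_lean" in g.failed_criteria for g in graded)

    def test_tandem_hold_with_flexion_and_adduction_passes(self):
        ex = default_exercises()["tandem_stance"]
        prof = MotionProfile("tandem_stance", n_reps=1, hold_s=16.0,
                             params={"peak_angle": 16.0, "adduction_deg": 6.0},
                             seed=3)
        seq = simulate_skeleton(prof)
        event = detect_attempts(seq, ex)[0]
        assert assess_quality(event, seq, ex).quality

    def test_tandem_without_adduction_fails(self):
        ex = default_exercises()["tandem_stance"]
        prof = MotionProfile("tandem_stance", n_reps=1, hold_s=16.0,
                             params={"peak_angle": 16.0, "adduction_deg": 0.5},
                             seed=3)
        seq = simulate_skeleton(prof)
        event = detect_attempts(seq, ex)[0]
        graded = assess_quality(event, seq, ex)
        assert not graded.quality and graded.failed_criteria

    def test_exercise_without_quality_rules_raises(self):
        ex = default_exercises()["kick"]
        prof = MotionProfile("kick", n_reps=1, seed=0)
        seq = simulate_skeleton(prof)
        event = detect_attempts(seq, ex)[0]
        with pytest.raises(ConfigurationError, match="kick"):
            assess_quality(event, seq, ex)

    def test_quality_count_never_exceeds_attempts(self):
        prof = MotionProfile("squat", n_reps=5, noise_sd=0.008, seed=17)
        seq = simulate_skeleton(prof)
        ex = default_exercises()["squat"]
        events = detect_attempts(seq, ex)
        graded = [assess_quality(e, seq, ex) for e in events]
        assert sum(g.quality for g in graded) <= len(events)


class TestTimeHold:
    def test_continuous_hold_times_full_duration(self):
        ex = default_exercises()["calf_stretch"]
        prof = MotionProfile("calf_stretch", n_reps=1, hold_s=30.0, seed=0)
        res = time_hold(simulate_skeleton(prof), ex)
        assert res.best_time == pytest.approx(30.0, abs=0.5)

    def test_best_time_is_max_of_attempts(self):
        ex = default_exercises()["single_leg_stance"]
        profs = MotionProfile("single_leg_stance", n_reps=3, hold_s=5.0, seed=0)
        seq = simulate_skeleton(profs)
        res = time_hold(seq, ex)
        assert len(res.attempt_times) == 3
        assert res.best_time == max(res.attempt_times)

    def test_only_first_three_qualifying_spans_count(self):
        ex = default_exercises()["single_leg_stance"]
        prof = MotionProfile("single_leg_stance", n_reps=4, hold_s=5.0, seed=0)
        res = time_hold(simulate_skeleton(prof), ex)
        assert len(res.attempt_times) == 3

    def test_repetition_exercise_rejected(self):
        ex = default_exercises()["squat"]
        prof = MotionProfile("squat", n_reps=1, seed=0)
        with pytest.raises(ModeError):
            time_hold(simulate_skeleton(prof), ex)


class TestSpeedWarnings:
    def test_static_stream_is_quiet(self, neutral_seq):
        assert speed_warnings(neutral_seq) == []

    def test_constant_velocity_interval_detected(self, neutral_seq):
        """One joint moving at 3 m/s for 1 s crosses a 2 m/s threshold."""
        seq = static_sequence(neutral_seq.xyz[0], n_frames=90)
        j = JOINT_INDEX["wrist_r"]
        moving = (seq.times >= 1.0) & (seq.times < 2.0)
        seq.xyz[moving, j, 0] += 3.0 * (seq.times[moving] - 1.0)
        intervals = speed_warnings(seq, threshold=2.0, min_duration=0.2)
        assert len(intervals) == 1
        t0, t1 = intervals[0]
        assert t1 - t0 == pytest.approx(1.0, abs=0.15)

    def test_brief_spike_filtered_by_min_duration(self, neutral_seq):
        seq = static_sequence(neutral_seq.xyz[0], n_frames=90)
        seq.xyz[45, JOINT_INDEX["wrist_r"], 0] += 0.5  # one-frame jump
        assert speed_warnings(seq, threshold=2.0, min_duration=0.2) == []


@settings(deadline=None, max_examples=25, derandomize=True)
@given(peak=st.floats(min_value=25.0, max_value=80.0),
       n_reps=st.integers(min_value=1, max_value=5))
def test_recovery_property_hip_flexion(peak, n_reps):
    """Noiseless constructed streams always yield the constructed count."""
    prof = MotionProfile("hip_flexion", n_reps=n_reps, peak_angle=peak, seed=1)
    assert len(detect_attempts(simulate_skeleton(prof), "hip_flexion")) == n_reps
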