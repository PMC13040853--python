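"""Joint-angle computation and rule-based repetition detection.

A depth camera reports the 3D positions of 19 body joints at a nominal
30 frames/s (x horizontal, y vertical, z depth/forward, all in meters).
From these streams the module computes anatomical angles (hip/knee flexion,
hip ab/adduction, lateral trunk lean), segments the stream into repetition
*attempts* using per-exercise movement-acceptability rules, grades each
attempt against *quality* rules, times static holds, and flags
excessive-speed intervals.

Detection is purely rule based: every exercise is described by a small set
of named scalar metrics (an angle or a displacement computed per frame)
together with a threshold for each. An attempt is a maximal excursion during
which all metrics simultaneously reach their thresholds; hysteresis (close at
50% of threshold, minimum 0.25 s between events) prevents chatter from
double-counting a single movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConfigurationError,
    MissingDataError,
    ModeError,
    UnsupportedExerciseError,
)

# --------------------------------------------------------------------------
# Canonical skeleton
# --------------------------------------------------------------------------

#: Canonical 19-joint vocabulary (5 axial + 7 per arm/leg pair).
JOINT_NAMES: tuple[str, ...] = (
    "head",
    "neck",
    "spine_shoulder",
    "spine_mid",
    "spine_base",
    "shoulder_l",
    "elbow_l",
    "wrist_l",
    "hand_l",
    "shoulder_r",
    "elbow_r",
    "wrist_r",
    "hand_r",
    "hip_l",
    "knee_l",
    "foot_l",
    "hip_r",
    "knee_r",
    "foot_r",
)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

#: Nominal capture rate of the tracking camera, frames per second.
FPS: float = 30.0

#: Longest marker gap (frames) bridged by linear interpolation.
MAX_INTERP_GAP: int = 5

#: Hysteresis: an open event closes when the driver falls below this
#: fraction of the attempt threshold.
HYSTERESIS_FRACTION: float = 0.5

#: Minimum time between the close of one event and the opening of the next.
MIN_EVENT_GAP_S: float = 0.25

#: Frames used to estimate the neutral-posture baseline at stream start.
BASELINE_FRAMES: int = 15

#: Boxcar width (frames) for smoothing driver metrics before detection.
SMOOTH_FRAMES: int = 5

#: Default speed-warning parameters.
SPEED_THRESHOLD_M_S: float = 2.0
SPEED_MIN_DURATION_S: float = 0.2


@dataclass
class SkeletonSequence:
    """A timestamped 19-joint 3D position stream for one exercise bout.

    Attributes
    ----------
    times : (n,) array of seconds, strictly increasing.
    xyz : (n, 19, 3) array of meters; NaN where the marker is missing.
    missing : (n, 19) boolean mask, True where the marker was not tracked.
    """

    times: np.ndarray
    xyz: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[1] != len(JOINT_NAMES) or self.xyz.shape[2] != 3:
            raise ValueError(f"xyz must have shape (n, 19, 3), got {self.xyz.shape}")
        if self.times.shape[0] != self.xyz.shape[0]:
            raise ValueError("times and xyz disagree on frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.missing is None:
            self.missing = np.any(np.isnan(self.xyz), axis=2)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def interpolated(self, max_gap: int = MAX_INTERP_GAP) -> "SkeletonSequence":
        """Fill marker gaps of up to ``max_gap`` frames by linear interpolation.

        Longer gaps (and gaps touching the stream edges) remain missing; frames
        inside them are excluded from event formation downstream.
        """
        xyz = self.xyz.copy()
        missing = self.missing.copy()
        n = self.n_frames
        for j in range(len(JOINT_NAMES)):
            mask = missing[:, j]
            if not mask.any() or mask.all():
                continue
            # locate runs of missing frames
            idx = np.flatnonzero(mask)
            splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            good = np.flatnonzero(~mask)
            for run in splits:
                if len(run) > max_gap:
                    continue
                lo, hi = run[0] - 1, run[-1] + 1
                if lo < 0 or hi >= n:
                    continue  # edge gap: nothing to anchor on
                t0, t1 = self.times[lo], self.times[hi]
                w = (self.times[run] - t0) / (t1 - t0)
                xyz[run, j, :] = (1 - w)[:, None] * xyz[lo, j, :] + w[:, None] * xyz[hi, j, :]
                missing[run, j] = False
            del good
        return SkeletonSequence(self.times, xyz, missing)


@dataclass
class ExerciseDefinition:
    """Prescription plus detection rules for one exercise.

    ``attempt_rules`` and ``quality_rules`` map metric names (see
    :data:`METRICS`) to thresholds; an attempt must reach every attempt
    threshold simultaneously, a high-quality repetition must additionally
    satisfy every quality rule. Exactly one of ``prescribed_reps`` /
    ``prescribed_time_s`` is set, matching ``mode``.
    """

    name: str
    mode: str = "reps"  # "reps" | "timed"
    prescribed_reps: int | None = 10
    prescribed_time_s: float | None = None
    sets: int = 1
    supported: bool = False
    laterality: str = "bilateral"  # "left" | "right" | "bilateral"
    attempt_rules: dict[str, float] = field(default_factory=dict)
    quality_rules: dict[str, float] = field(default_factory=dict)
    quality_checker: str | None = None  # key into QUALITY_CHECKERS

    def __post_init__(self) -> None:
        if self.mode not in ("reps", "timed"):
            raise ConfigurationError(f"unknown mode {self.mode!r} for exercise {self.name!r}")
        if self.mode == "reps":
            if self.prescribed_reps is None:
                raise ConfigurationError(f"{self.name}: repetition mode needs prescribed_reps")
            self.prescribed_time_s = None
        else:
            if self.prescribed_time_s is None:
                raise ConfigurationError(f"{self.name}: timed mode needs prescribed_time_s")
            self.prescribed_reps = None
        for rule, thr in {**self.attempt_rules, **self.quality_rules}.items():
            if rule.endswith("_deg") and not (0 < thr < 180):
                raise ConfigurationError(
                    f"{self.name}: angle threshold {rule}={thr} outside (0, 180)"
                )

    @property
    def prescribed_total(self) -> float:
        """Total prescription across sets (reps or seconds)."""
        if self.mode == "reps":
            return float(self.prescribed_reps * self.sets)
        return float(self.prescribed_time_s * self.sets)

    @property
    def sides(self) -> tuple[str, ...]:
        """Detection sides: bilateral exercises count left and right
        excursions separately; symmetric whole-body movements (squat,
        sit-to-stand...) are detected once."""
        if self.laterality == "bilateral":
            return ("l", "r")
        if self.laterality == "symmetric":
            return ("l",)
        return (self.laterality[0],)


@dataclass
class RepetitionEvent:
    """One detected movement excursion."""

    start_time: float
    peak_time: float
    end_time: float
    side: str = "l"
    attempt: bool = True
    quality: bool | None = None
    failed_criteria: list[str] = field(default_factory=list)
    peak_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.start_time < self.peak_time < self.end_time):
            raise ValueError("event must satisfy start < peak < end")


@dataclass
class HoldResult:
    """Timed-exercise outcome: up to three hold attempts in a 120 s window."""

    attempt_times: list[float]
    window_used: float

    @property
    def best_time(self) -> float:
        return max(self.attempt_times) if self.attempt_times else 0.0


#: Cap on hold attempts and assessment window for timed exercises.
MAX_HOLD_ATTEMPTS: int = 3
HOLD_WINDOW_S: float = 120.0


# --------------------------------------------------------------------------
# Angle and displacement metrics
# --------------------------------------------------------------------------

def _positions(seq: SkeletonSequence, name: str) -> np.ndarray:
    return seq.xyz[:, JOINT_INDEX[name], :]


def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Elementwise angle (degrees) between rows of u and v."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def _trunk_vector(seq: SkeletonSequence) -> np.ndarray:
    return _positions(seq, "spine_shoulder") - _positions(seq, "spine_base")


def hip_flexion_series(seq: SkeletonSequence, side: str) -> np.ndarray:
    """Hip flexion (deg): 180° minus the trunk-to-thigh angle; 0 standing."""
    thigh = _positions(seq, f"knee_{side}") - _positions(seq, f"hip_{side}")
    return 180.0 - _angle_between(_trunk_vector(seq), thigh)


def knee_flexion_series(seq: SkeletonSequence, side: str) -> np.ndarray:
    """Knee flexion (deg): 180° minus the interior hip-knee-foot angle."""
    knee = _positions(seq, f"knee_{side}")
    up = _positions(seq, f"hip_{side}") - knee
    down = _positions(seq, f"foot_{side}") - knee
    return 180.0 - _angle_between(up, down)


def hip_frontal_series(seq: SkeletonSequence, side: str) -> np.ndarray:
    """Signed frontal-plane thigh angle (deg): + abduction, − adduction.

    Measured in the x–y plane between the thigh and the downward trunk axis;
    positive when the knee moves away from the body midline.
    """
    thigh = _positions(seq, f"knee_{side}") - _positions(seq, f"hip_{side}")
    down = -_trunk_vector(seq)
    t2 = thigh[:, :2]  # x, y
    d2 = down[:, :2]
    ang = _angle_between(t2, d2)
    side_sign = -1.0 if side == "l" else 1.0
    # away from midline: left thigh swings to -x, right thigh to +x
    away = np.where(t2[:, 0] * side_sign >= 0, 1.0, -1.0)
    return ang * away


def trunk_lean_series(seq: SkeletonSequence) -> np.ndarray:
    """Lateral trunk lean (deg): frontal-plane tilt of the spine from vertical.

    Pure sagittal (forward) tilt projects onto the vertical and reads 0.
    """
    s = _trunk_vector(seq)
    return np.degrees(np.arctan2(np.abs(s[:, 0]), s[:, 1]))


def _baseline(values: np.ndarray) -> float:
    head = values[:BASELINE_FRAMES]
    head = head[~np.isnan(head)]
    if head.size == 0:
        return np.nan
    return float(np.median(head))


def _metric_hip_flexion(seq, side):
    return hip_flexion_series(seq, side)


def _metric_knee_flexion(seq, side):
    return knee_flexion_series(seq, side)


def _metric_hip_abduction(seq, side):
    return hip_frontal_series(seq, side)


def _metric_hip_adduction(seq, side):
    return -hip_frontal_series(seq, side)


def _metric_chest_drop(seq, side):
    y = _positions(seq, "spine_shoulder")[:, 1]
    return _baseline(y) - y


def _metric_chest_forward(seq, side):
    z = _positions(seq, "spine_shoulder")[:, 2]
    return z - _baseline(z)


def _metric_foot_lead(seq, side):
    other = "r" if side == "l" else "l"
    return _positions(seq, f"foot_{side}")[:, 2] - _positions(seq, f"foot_{other}")[:, 2]


def _metric_foot_back(seq, side):
    return -_metric_foot_lead(seq, side)


def _metric_foot_beyond_shoulder(seq, side):
    sgn = -1.0 if side == "l" else 1.0
    foot = _positions(seq, f"foot_{side}")[:, 0] * sgn
    shoulder = _positions(seq, f"shoulder_{side}")[:, 0] * sgn
    return foot - shoulder


def _metric_foot_lift(seq, side):
    y = _positions(seq, f"foot_{side}")[:, 1]
    return y - _baseline(y)


def _metric_foot_anterior(seq, side):
    return _positions(seq, f"foot_{side}")[:, 2] - _positions(seq, "spine_base")[:, 2]


def _metric_arm_lateral(seq, side):
    sgn = -1.0 if side == "l" else 1.0
    x = _positions(seq, f"wrist_{side}")[:, 0] * sgn
    return x - _baseline(x)


def _metric_foot_lateral(seq, side):
    sgn = -1.0 if side == "l" else 1.0
    x = _positions(seq, f"foot_{side}")[:, 0] * sgn
    return x - _baseline(x)


#: Per-frame scalar metrics available to attempt/quality rules. Angle metrics
#: carry a ``_deg`` suffix, displacement metrics an ``_m`` suffix.
METRICS = {
    "hip_flexion_deg": _metric_hip_flexion,
    "knee_flexion_deg": _metric_knee_flexion,
    "hip_abduction_deg": _metric_hip_abduction,
    "hip_adduction_deg": _metric_hip_adduction,
    "chest_drop_m": _metric_chest_drop,
    "chest_forward_m": _metric_chest_forward,
    "foot_lead_m": _metric_foot_lead,
    "foot_back_m": _metric_foot_back,
    "foot_beyond_shoulder_m": _metric_foot_beyond_shoulder,
    "foot_lift_m": _metric_foot_lift,
    "foot_anterior_m": _metric_foot_anterior,
    "arm_lateral_m": _metric_arm_lateral,
    "foot_lateral_m": _metric_foot_lateral,
}

#: Markers each named angle depends on (for missing-data diagnostics).
_ANGLE_MARKERS = {
    "hip_flexion": ("spine_base", "spine_shoulder", "hip_{s}", "knee_{s}"),
    "knee_flexion": ("hip_{s}", "knee_{s}", "foot_{s}"),
    "hip_abduction": ("spine_base", "spine_shoulder", "hip_{s}", "knee_{s}"),
    "hip_adduction": ("spine_base", "spine_shoulder", "hip_{s}", "knee_{s}"),
    "trunk_lean": ("spine_base", "spine_shoulder"),
}


def joint_angle(seq: SkeletonSequence, frame: int, angle_name: str, side: str = "l") -> float:
    """Named anatomical angle (degrees) at a single frame.

    Flexion angles are zero at anatomical neutral (standing straight).
    Raises :class:`MissingDataError` naming the frame and markers if the
    defining markers are missing (after interpolation has been applied).
    """
    base = angle_name
    if angle_name.endswith(("_l", "_r")):
        base, side = angle_name[:-2], angle_name[-1]
    if base not in _ANGLE_MARKERS:
        raise ConfigurationError(f"unknown angle {angle_name!r}")
    markers = [m.format(s=side) for m in _ANGLE_MARKERS[base]]
    gone = [m for m in markers if seq.missing[frame, JOINT_INDEX[m]]]
    if gone:
        raise MissingDataError(f"frame {frame}: missing markers {gone} for {angle_name}")
    if base == "trunk_lean":
        return float(trunk_lean_series(seq)[frame])
    fn = {"hip_flexion": hip_flexion_series,
          "knee_flexion": knee_flexion_series,
          "hip_abduction": hip_frontal_series,
          "hip_adduction": lambda s, sd: -hip_frontal_series(s, sd)}[base]
    return float(fn(seq, side)[frame])


def trunk_lean(seq: SkeletonSequence, frame: int) -> float:
    """Lateral trunk lean (deg) at one frame; see :func:`trunk_lean_series`."""
    return joint_angle(seq, frame, "trunk_lean")


# --------------------------------------------------------------------------
# Default exercise rule set
# --------------------------------------------------------------------------

def _squat_quality(event: RepetitionEvent, seq: SkeletonSequence,
                   ex: ExerciseDefinition) -> list[str]:
    """Squat quality rules: depth band on hip/knee flexion at the lowest
    position, lateral trunk lean, shoulder-width unmoving feet, knees apart
    and over the feet."""
    q = ex.quality_rules
    lo = q.get("depth_low_deg", 70.0)
    hi = q.get("depth_high_deg", 110.0)
    lean_max = q.get("trunk_lean_max_deg", 10.0)
    sep_tol = q.get("foot_sep_tol_frac", 0.25)
    move_max = q.get("foot_move_max_m", 0.05)
    knee_sep_min = q.get("knee_min_sep_m", 0.08)
    align_max = q.get("knee_foot_align_max_m", 0.10)

    i0 = int(np.searchsorted(seq.times, event.start_time))
    i1 = int(np.searchsorted(seq.times, event.end_time, side="right"))
    sl = slice(i0, i1)
    failed: list[str] = []

    hip = np.nanmax((hip_flexion_series(seq, "l")[sl] + hip_flexion_series(seq, "r")[sl]) / 2)
    knee = np.nanmax((knee_flexion_series(seq, "l")[sl] + knee_flexion_series(seq, "r")[sl]) / 2)
    if not (lo <= hip <= hi):
        failed.append("hip_depth")
    if not (lo <= knee <= hi):
        failed.append("knee_depth")
    if np.nanmax(trunk_lean_series(seq)[sl]) >= lean_max:
        failed.append("trunk_lean")

    feet_l = _positions(seq, "foot_l")[sl]
    feet_r = _positions(seq, "foot_r")[sl]
    foot_sep = np.nanmean(np.abs(feet_l[:, 0] - feet_r[:, 0]))
    shoulder_sep = np.nanmean(np.abs(
        _positions(seq, "shoulder_l")[sl][:, 0] - _positions(seq, "shoulder_r")[sl][:, 0]))
    if not ((1 - sep_tol) * shoulder_sep <= foot_sep <= (1 + sep_tol) * shoulder_sep):
        failed.append("foot_separation")
    move = max(np.nanmax(np.linalg.norm(feet_l - feet_l[0], axis=1)),
               np.nanmax(np.linalg.norm(feet_r - feet_r[0], axis=1)))
    if move >= move_max:
        failed.append("feet_unmoving")

    knees_l = _positions(seq, "knee_l")[sl]
    knees_r = _positions(seq, "knee_r")[sl]
    if np.nanmin(np.linalg.norm(knees_l - knees_r, axis=1)) <= knee_sep_min:
        failed.append("knees_touching")
    align = max(np.nanmax(np.abs(knees_l[:, 0] - feet_l[:, 0])),
                np.nanmax(np.abs(knees_r[:, 0] - feet_r[:, 0])))
    if align >= align_max:
        failed.append("knees_over_ankles")
    return failed


def _threshold_quality(event: RepetitionEvent, seq: SkeletonSequence,
                       ex: ExerciseDefinition) -> list[str]:
    """Generic quality check: every quality-rule metric must reach its
    threshold simultaneously at some frame inside the event (for repetition
    exercises) or contiguously for the prescribed time (timed exercises)."""
    i0 = int(np.searchsorted(seq.times, event.start_time))
    i1 = int(np.searchsorted(seq.times, event.end_time, side="right"))
    score = _rule_score(seq, ex.quality_rules, event.side)[i0:i1]
    if ex.mode == "reps":
        return [] if np.any(score >= 1.0) else sorted(ex.quality_rules)
    # timed: need a contiguous qualifying span at least as long as prescribed
    need = ex.prescribed_time_s or 0.0
    spans = _qualifying_spans(seq.times[i0:i1], score)
    ok = any(dur >= need - 1.0 / FPS for _, _, dur in spans)
    return [] if ok else sorted(ex.quality_rules)


QUALITY_CHECKERS = {
    "squat": _squat_quality,
    "threshold": _threshold_quality,
}


def default_exercises() -> dict[str, ExerciseDefinition]:
    """The supported rule set: 13 exercises with their attempt metrics.

    Angle thresholds follow the published movement-acceptability criteria
    (e.g. at least 20° of hip flexion for a leg lift); displacement
    thresholds operationalize qualitative criteria (staggered stance, foot
    beyond shoulder) with configurable defaults in meters.
    """
    defs = [
        ExerciseDefinition(
            "hip_flexion", laterality="bilateral",
            attempt_rules={"hip_flexion_deg": 20.0}),
        ExerciseDefinition(
            "hip_abduction", laterality="bilateral",
            attempt_rules={"hip_abduction_deg": 20.0}),
        ExerciseDefinition(
            "forward_step", laterality="bilateral",
            attempt_rules={"foot_lead_m": 0.15}),
        ExerciseDefinition(
            "lateral_step", laterality="bilateral",
            attempt_rules={"foot_beyond_shoulder_m": 0.05}),
        ExerciseDefinition(
            "backward_step", laterality="bilateral",
            attempt_rules={"foot_back_m": 0.20}),
        ExerciseDefinition(
            "tandem_stance", mode="timed", prescribed_time_s=15.0,
            laterality="bilateral",
            attempt_rules={"foot_lead_m": 0.20},
            quality_rules={"hip_flexion_deg": 15.0, "hip_adduction_deg": 5.0},
            quality_checker="threshold"),
        ExerciseDefinition(
            "single_leg_stance", mode="timed", prescribed_time_s=10.0,
            laterality="bilateral",
            attempt_rules={"foot_lift_m": 0.05}),
        ExerciseDefinition(
            "sit_to_stand", laterality="symmetric",
            attempt_rules={"chest_drop_m": 0.10}),
        ExerciseDefinition(
            "calf_stretch", mode="timed", prescribed_time_s=30.0,
            laterality="bilateral",
            attempt_rules={"foot_back_m": 0.15}),
        ExerciseDefinition(
            "hamstring_stretch", mode="timed", prescribed_time_s=30.0,
            laterality="symmetric",
            attempt_rules={"chest_forward_m": 0.10}),
        ExerciseDefinition(
            "squat", laterality="symmetric",
            attempt_rules={"chest_drop_m": 0.10,
                           "hip_flexion_deg": 20.0,
                           "knee_flexion_deg": 20.0},
            quality_rules={"depth_low_deg": 70.0, "depth_high_deg": 110.0,
                           "trunk_lean_max_deg": 10.0},
            quality_checker="squat"),
        ExerciseDefinition(
            "seated_star_jump", laterality="bilateral",
            attempt_rules={"arm_lateral_m": 0.10, "foot_lateral_m": 0.10}),
        ExerciseDefinition(
            "kick", laterality="bilateral",
            attempt_rules={"foot_anterior_m": 0.15}),
    ]
    return {d.name: d for d in defs}


SUPPORTED_EXERCISES: tuple[str, ...] = tuple(default_exercises())


# --------------------------------------------------------------------------
# Event detection
# --------------------------------------------------------------------------

def _smooth(x: np.ndarray, width: int = SMOOTH_FRAMES) -> np.ndarray:
    """NaN-preserving boxcar smoothing of a driver metric."""
    if width <= 1 or x.size < width:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    nan = np.isnan(xp)
    filled = np.where(nan, 0.0, xp)
    weight = np.convolve(~nan, kernel, mode="same")
    out = np.convolve(filled, kernel, mode="same") / np.where(weight > 0, weight, np.nan)
    out = out[pad:pad + x.size]
    out[np.isnan(x)] = np.nan
    return out


def _rule_score(seq: SkeletonSequence, rules: dict[str, float], side: str,
                smooth: int = SMOOTH_FRAMES) -> np.ndarray:
    """Normalized driver: min over rules of metric/threshold.

    A frame scores >= 1 exactly when every rule is simultaneously satisfied.
    NaN (unresolvable missing markers) propagates and breaks events.
    """
    if not rules:
        raise ConfigurationError("empty rule set")
    score = None
    for metric, thr in rules.items():
        if metric not in METRICS:
            raise ConfigurationError(f"unknown metric {metric!r}")
        if thr <= 0:
            raise ConfigurationError(f"threshold for {metric} must be > 0")
        m = _smooth(METRICS[metric](seq, side), smooth) / thr
        score = m if score is None else np.minimum(score, m)
    return score


def _detect_on_score(times: np.ndarray, score: np.ndarray) -> list[tuple[int, int, int]]:
    """Hysteresis event segmentation on a normalized driver.

    Returns (start, peak, end) frame indices. An event opens when the score
    reaches 1, closes when it drops below the hysteresis level (or hits a
    missing-data NaN), and a new event may only open MIN_EVENT_GAP_S after
    the previous close.
    """
    events: list[tuple[int, int, int]] = []
    open_i: int | None = None
    last_close_t = -np.inf
    s = np.where(np.isnan(score), -np.inf, score)
    for i in range(len(s)):
        if open_i is None:
            if s[i] >= 1.0 and times[i] - last_close_t >= MIN_EVENT_GAP_S:
                open_i = i
        else:
            if s[i] < HYSTERESIS_FRACTION:
                peak = open_i + int(np.argmax(s[open_i:i])) if i > open_i else open_i
                events.append((max(open_i - 1, 0), peak, i))
                last_close_t = times[i]
                open_i = None
    if open_i is not None:
        peak = open_i + int(np.argmax(s[open_i:]))
        events.append((max(open_i - 1, 0), peak, len(s) - 1))
    return events


def detect_attempts(seq: SkeletonSequence,
                    exercise: ExerciseDefinition | str) -> list[RepetitionEvent]:
    """Detect attempted repetitions in a stream.

    Returns maximal non-overlapping events ordered by start time, each
    satisfying all attempt rules of the exercise at its peak. For bilateral
    exercises, left and right excursions are detected independently and
    merged, so alternating leg lifts count as separate attempts.
    """
    if isinstance(exercise, str):
        catalog = default_exercises()
        if exercise not in catalog:
            raise UnsupportedExerciseError(f"unsupported exercise {exercise!r}")
        exercise = catalog[exercise]
    if not exercise.attempt_rules:
        raise UnsupportedExerciseError(
            f"exercise {exercise.name!r} has no attempt rules")
    if seq.duration < 1.0:
        raise MissingDataError("stream must cover at least 1 s")
    if seq.missing.all():
        raise MissingDataError("all markers missing for the whole stream")
    seq = seq.interpolated()

    events: list[RepetitionEvent] = []
    for side in exercise.sides:
        score = _rule_score(seq, exercise.attempt_rules, side)
        for i0, ip, i1 in _detect_on_score(seq.times, score):
            peak_values = {
                m: float(_smooth(METRICS[m](seq, side))[ip])
                for m in exercise.attempt_rules
            }
            start_t, end_t = float(seq.times[i0]), float(seq.times[i1])
            peak_t = float(seq.times[ip])
            if not (start_t < peak_t < end_t):
                peak_t = (start_t + end_t) / 2
            events.append(RepetitionEvent(
                start_time=start_t,
                peak_time=peak_t,
                end_time=end_t,
                side=side,
                attempt=True,
                peak_values=peak_values,
            ))
    events.sort(key=lambda e: e.start_time)
    return events


def assess_quality(event: RepetitionEvent, seq: SkeletonSequence,
                   exercise: ExerciseDefinition) -> RepetitionEvent:
    """Grade an attempt against the exercise's quality rules.

    Quality is true iff every quality rule passes; ``failed_criteria`` names
    each failed rule. Exercises without quality rules raise
    :class:`ConfigurationError` (full quality criteria are published only
    for a subset of exercises; the checker registry accepts more).
    """
    if not event.attempt:
        raise ValueError("quality is only assessed on attempts")
    if not exercise.quality_rules:
        raise ConfigurationError(
            f"exercise {exercise.name!r} has no quality rules configured")
    checker = QUALITY_CHECKERS[exercise.quality_checker or "threshold"]
    failed = checker(event, seq.interpolated(), exercise)
    return replace(event, quality=not failed, failed_criteria=failed)


def _qualifying_spans(times: np.ndarray, score: np.ndarray) -> list[tuple[float, float, float]]:
    """Contiguous spans with score >= 1: (start_t, end_t, duration)."""
    ok = np.where(np.isnan(score), False, score >= 1.0)
    spans = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            spans.append((float(times[start]), float(times[i - 1]),
                          float(times[i - 1] - times[start])))
            start = None
    if start is not None:
        spans.append((float(times[start]), float(times[-1]),
                      float(times[-1] - times[start])))
    return spans


def time_hold(seq: SkeletonSequence, exercise: ExerciseDefinition) -> HoldResult:
    """Time a static (timed) exercise: best of up to three hold attempts
    within a 120 s window.

    Hold criteria are the quality rules when configured, otherwise the
    attempt rules; a hold attempt is a contiguous span meeting all criteria.
    """
    if exercise.mode != "timed":
        raise ModeError(f"{exercise.name!r} is not a timed exercise")
    seq = seq.interpolated()
    rules = exercise.quality_rules or exercise.attempt_rules
    score = None
    for side in exercise.sides:
        s = _rule_score(seq, rules, side)
        score = s if score is None else np.fmax(score, s)
    spans = _qualifying_spans(seq.times, score)
    window_used = min(HOLD_WINDOW_S, seq.duration)
    t_end = seq.times[0] + window_used
    in_window = [sp for sp in spans if sp[0] < t_end]
    attempts = [sp[2] for sp in in_window[:MAX_HOLD_ATTEMPTS]]
    return HoldResult(attempt_times=attempts, window_used=float(window_used))


def speed_warnings(seq: SkeletonSequence,
                   threshold: float = SPEED_THRESHOLD_M_S,
                   min_duration: float = SPEED_MIN_DURATION_S) -> list[tuple[float, float]]:
    """Intervals where any joint's speed exceeds ``threshold`` (m/s) for at
    least ``min_duration`` seconds.

    Speed is the central-difference magnitude of each joint's position;
    mirrors the in-game slow-down warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    seq = seq.interpolated()
    t = seq.times
    if seq.n_frames < 3:
        return []
    vel = np.full((seq.n_frames, len(JOINT_NAMES)), np.nan)
    dt = (t[2:] - t[:-2])[:, None]
    disp = np.linalg.norm(seq.xyz[2:] - seq.xyz[:-2], axis=2)
    vel[1:-1] = disp / dt
    import warnings as _warnings
    with _warnings.catch_warnings():
        # first/last frames have no central difference: all-NaN rows expected
        _warnings.simplefilter("ignore", RuntimeWarning)
        vmax = np.nanmax(vel, axis=1)
    fast = np.where(np.isnan(vmax), False, vmax > threshold)
    out = []
    start = None
    for i, flag in enumerate(fast):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if t[i - 1] - t[start] >= min_duration:
                out.append((float(t[start]), float(t[i - 1])))
            start = None
    if start is not None and t[-1] - t[start] >= min_duration:
        out.append((float(t[start]), float(t[-1])))
    return out
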