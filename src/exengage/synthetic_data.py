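"""Synthetic study data: skeleton streams, session series, rater counts.

No raw study data are published, so this module generates inputs with the
statistical structure the analysis assumes:

* :func:`simulate_skeleton` — a 30 frames/s 19-joint stream for one exercise
  bout. Each repetition drives one or two anatomical angles (or segment
  displacements) with a raised-cosine pulse through a stick-figure pose
  model with fixed child-scaled segment lengths, so the noiseless angle
  traces are exactly controllable. Camera jitter is additive isotropic
  Gaussian noise on joint positions; dropouts are whole frames with all
  markers missing.
* :func:`simulate_atd_sessions` — an alternating-treatments session series
  with a controllable feedback effect on adherence; ``feedback_delta = 0``
  defines the exchangeable null used for type-I-error calibration.
* :func:`simulate_rater_counts` — paired manual/system repetition counts
  with rater noise and system bias, for agreement statistics.

All randomness flows from the single seed stated in the profile/spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engagement import CONDITIONS, SessionRecord
from .errors import ScheduleError, UnsupportedExerciseError
from .kinematics import (
    FPS,
    JOINT_INDEX,
    JOINT_NAMES,
    SUPPORTED_EXERCISES,
    SkeletonSequence,
)

# --------------------------------------------------------------------------
# Stick-figure geometry (meters, child-scaled defaults)
# --------------------------------------------------------------------------

DEFAULT_GEOMETRY = {
    "shank": 0.40,
    "thigh": 0.40,
    "trunk": 0.40,       # spine_base -> spine_shoulder
    "hip_half_width": 0.10,
    "shoulder_half_width": 0.16,
    "neck": 0.08,
    "head": 0.12,
    "upper_arm": 0.25,
    "forearm": 0.22,
    "hand": 0.08,
    "foot_height": 0.05,
}


def _neutral_pose(geom: dict[str, float], stance_half_width: float | None = None) -> np.ndarray:
    """Standing pose, y up, facing +z, origin under the body center."""
    g = geom
    w = stance_half_width if stance_half_width is not None else g["hip_half_width"]
    fy = g["foot_height"]
    hip_y = fy + g["shank"] + g["thigh"]
    base_y = hip_y + 0.05
    sh_y = base_y + g["trunk"]
    pose = np.zeros((len(JOINT_NAMES), 3))

    def put(name, x, y, z=0.0):
        pose[JOINT_INDEX[name]] = (x, y, z)

    put("spine_base", 0.0, base_y)
    put("spine_mid", 0.0, (base_y + sh_y) / 2)
    put("spine_shoulder", 0.0, sh_y)
    put("neck", 0.0, sh_y + g["neck"])
    put("head", 0.0, sh_y + g["neck"] + g["head"])
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        put(f"shoulder_{side}", sgn * g["shoulder_half_width"], sh_y)
        put(f"elbow_{side}", sgn * (g["shoulder_half_width"] + 0.02),
            sh_y - g["upper_arm"])
        put(f"wrist_{side}", sgn * (g["shoulder_half_width"] + 0.04),
            sh_y - g["upper_arm"] - g["forearm"])
        put(f"hand_{side}", sgn * (g["shoulder_half_width"] + 0.04),
            sh_y - g["upper_arm"] - g["forearm"] - g["hand"])
        put(f"hip_{side}", sgn * g["hip_half_width"], hip_y)
        put(f"knee_{side}", sgn * w, fy + g["shank"])
        put(f"foot_{side}", sgn * w, fy)
    # keep hips over the feet laterally for a plausible stance
    pose[JOINT_INDEX["hip_l"], 0] = -w
    pose[JOINT_INDEX["hip_r"], 0] = w
    return pose


def _leg(pose: np.ndarray, geom: dict[str, float], side: str,
         flex_deg: float, lateral_deg: float = 0.0) -> None:
    """Rotate one straight leg at the hip: sagittal flexion (forward) plus a
    signed frontal angle (positive away from the midline, negative toward)."""
    th = np.radians(flex_deg)
    sgn = -1.0 if side == "l" else 1.0
    # frontal rotation about z; 'away' points to -x for the left leg, +x right
    al = np.radians(lateral_deg) * sgn
    d = np.array([np.cos(th) * np.sin(al),
                  -np.cos(th) * np.cos(al),
                  np.sin(th)])
    hip = pose[JOINT_INDEX[f"hip_{side}"]]
    pose[JOINT_INDEX[f"knee_{side}"]] = hip + geom["thigh"] * d
    pose[JOINT_INDEX[f"foot_{side}"]] = hip + (geom["thigh"] + geom["shank"]) * d


#: Per-exercise pose defaults: peak driver values used when the profile does
#: not override them. Angles in degrees, displacements in meters.
POSE_DEFAULTS: dict[str, dict[str, float]] = {
    "hip_flexion": {"peak_angle": 45.0},
    "hip_abduction": {"peak_angle": 30.0},
    "forward_step": {"step_m": 0.25},
    "lateral_step": {"step_m": 0.25},
    "backward_step": {"step_m": 0.30},
    "tandem_stance": {"peak_angle": 20.0, "adduction_deg": 6.0},
    "single_leg_stance": {"lift_m": 0.15},
    "sit_to_stand": {"drop_m": 0.25},
    "calf_stretch": {"step_m": 0.25},
    "hamstring_stretch": {"reach_m": 0.20},
    "squat": {"peak_angle": 90.0, "trunk_lean_deg": 0.0, "stance_half_width": 0.16},
    "seated_star_jump": {"arm_m": 0.20, "foot_m": 0.20},
    "kick": {"peak_angle": 45.0},
}

_TIMED = {"tandem_stance", "single_leg_stance", "calf_stretch", "hamstring_stretch"}

_UPPER_BODY = ["head", "neck", "spine_shoulder", "spine_mid", "spine_base",
               "shoulder_l", "elbow_l", "wrist_l", "hand_l",
               "shoulder_r", "elbow_r", "wrist_r", "hand_r"]
_ABOVE_KNEE = _UPPER_BODY + ["hip_l", "hip_r"]


@dataclass
class MotionProfile:
    """Generation recipe for one synthetic exercise bout."""

    exercise_name: str
    n_reps: int = 5
    rep_period: float = 2.0
    peak_angle: float | None = None   # overrides the exercise default driver
    baseline_angle: float = 0.0
    noise_sd: float = 0.0             # meters, isotropic on joint positions
    dropout_rate: float = 0.0         # probability a frame loses all markers
    seed: int = 0
    hold_s: float = 5.0               # plateau duration for timed exercises
    lead_in_s: float = 1.0            # neutral posture before the first rep
    tail_s: float = 0.5
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exercise_name not in SUPPORTED_EXERCISES:
            raise UnsupportedExerciseError(
                f"unsupported exercise {self.exercise_name!r}")
        if self.n_reps < 0 or self.rep_period <= 0:
            raise ValueError("n_reps must be >= 0 and rep_period > 0")
        if self.noise_sd < 0 or not (0 <= self.dropout_rate <= 1):
            raise ValueError("invalid noise_sd or dropout_rate")
        if (self.peak_angle is not None and self.baseline_angle is not None
                and "peak_angle" in POSE_DEFAULTS[self.exercise_name]
                and self.peak_angle <= self.baseline_angle):
            raise ValueError("peak_angle must exceed baseline_angle")

    def pose_params(self) -> dict[str, float]:
        p = dict(POSE_DEFAULTS[self.exercise_name])
        if self.peak_angle is not None and "peak_angle" in p:
            p["peak_angle"] = self.peak_angle
        p.update(self.params)
        return p


def _pose_at(exercise: str, u: float, side: str, p: dict[str, float],
             geom: dict[str, float]) -> np.ndarray:
    """Stick-figure pose at pulse amplitude u in [0, 1]."""
    stance = p.get("stance_half_width")
    pose = _neutral_pose(geom, stance)
    sgn = -1.0 if side == "l" else 1.0
    if exercise == "hip_flexion" or exercise == "kick":
        _leg(pose, geom, side, u * p["peak_angle"])
    elif exercise == "hip_abduction":
        _leg(pose, geom, side, 0.0, u * p["peak_angle"])
    elif exercise == "tandem_stance":
        _leg(pose, geom, side, u * p["peak_angle"], -u * p["adduction_deg"])
    elif exercise in ("forward_step", "backward_step", "calf_stretch"):
        dz = u * p["step_m"] * (1.0 if exercise == "forward_step" else -1.0)
        pose[JOINT_INDEX[f"foot_{side}"], 2] += dz
        pose[JOINT_INDEX[f"knee_{side}"], 2] += dz / 2
    elif exercise == "lateral_step":
        dx = sgn * u * p["step_m"]
        pose[JOINT_INDEX[f"foot_{side}"], 0] += dx
        pose[JOINT_INDEX[f"knee_{side}"], 0] += dx / 2
    elif exercise == "single_leg_stance":
        dy = u * p["lift_m"]
        pose[JOINT_INDEX[f"foot_{side}"], 1] += dy
        pose[JOINT_INDEX[f"knee_{side}"], 1] += dy / 2
    elif exercise == "sit_to_stand":
        for j in _ABOVE_KNEE:
            pose[JOINT_INDEX[j], 1] -= u * p["drop_m"]
    elif exercise == "hamstring_stretch":
        for j in ("spine_shoulder", "neck", "head", "shoulder_l", "shoulder_r"):
            pose[JOINT_INDEX[j], 2] += u * p["reach_m"]
    elif exercise == "squat":
        th = np.radians(u * p["peak_angle"])
        drop = geom["thigh"] * (1 - np.cos(th))
        back = geom["thigh"] * np.sin(th)
        lean = np.radians(p.get("trunk_lean_deg", 0.0))
        for s2 in ("l", "r"):
            foot = pose[JOINT_INDEX[f"foot_{s2}"]].copy()
            knee = foot + np.array([0.0, geom["shank"], 0.0])
            hip = knee + np.array([0.0, geom["thigh"] * np.cos(th),
                                   -geom["thigh"] * np.sin(th)])
            pose[JOINT_INDEX[f"knee_{s2}"]] = knee
            pose[JOINT_INDEX[f"hip_{s2}"]] = hip
        for j in _UPPER_BODY:
            pose[JOINT_INDEX[j], 1] -= drop
            pose[JOINT_INDEX[j], 2] -= back
        if lean != 0.0:
            base = pose[JOINT_INDEX["spine_base"]].copy()
            c, s = np.cos(lean), np.sin(lean)
            for j in _UPPER_BODY:
                if j == "spine_base":
                    continue
                v = pose[JOINT_INDEX[j]] - base
                pose[JOINT_INDEX[j]] = base + np.array(
                    [v[0] * c - v[1] * s, v[0] * s + v[1] * c, v[2]])
    elif exercise == "seated_star_jump":
        for j in (f"wrist_{side}", f"hand_{side}", f"elbow_{side}"):
            pose[JOINT_INDEX[j], 0] += sgn * u * p["arm_m"]
        pose[JOINT_INDEX[f"foot_{side}"], 0] += sgn * u * p["foot_m"]
        pose[JOINT_INDEX[f"knee_{side}"], 0] += sgn * u * p["foot_m"] / 2
    else:  # pragma: no cover - guarded by MotionProfile validation
        raise UnsupportedExerciseError(exercise)
    return pose


def _pulse_train(profile: MotionProfile) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Times, pulse amplitude u(t) in [0,1], and active rep index per frame."""
    timed = profile.exercise_name in _TIMED
    ramp, rest = 0.5, 0.75
    period = (2 * ramp + profile.hold_s + rest) if timed else profile.rep_period
    total = profile.lead_in_s + profile.n_reps * period + profile.tail_s
    n = max(int(np.round(total * FPS)) + 1, int(1.5 * FPS))
    t = np.arange(n) / FPS
    u = np.zeros(n)
    rep = np.full(n, -1)
    for k in range(profile.n_reps):
        t0 = profile.lead_in_s + k * period
        local = t - t0
        if timed:
            up = (local >= 0) & (local < ramp)
            hold = (local >= ramp) & (local < ramp + profile.hold_s)
            down = (local >= ramp + profile.hold_s) & (local < 2 * ramp + profile.hold_s)
            u[up] = local[up] / ramp
            u[hold] = 1.0
            u[down] = 1.0 - (local[down] - ramp - profile.hold_s) / ramp
            active = up | hold | down
        else:
            active = (local >= 0) & (local < period)
            u[active] = 0.5 * (1 - np.cos(2 * np.pi * local[active] / period))
        rep[active] = k
    return t, u, rep


def simulate_skeleton(profile: MotionProfile,
                      geometry: dict[str, float] | None = None) -> SkeletonSequence:
    """Generate a 30 frames/s skeleton stream for one exercise bout.

    The noiseless driver trace crosses the profile's peak exactly ``n_reps``
    times, returning to baseline between repetitions; bilateral exercises
    alternate left/right. Noise is additive Gaussian on positions and
    dropouts blank whole frames. Identical profiles (including seed) yield
    bit-identical streams.
    """
    geom = {**DEFAULT_GEOMETRY, **(geometry or {})}
    p = profile.pose_params()
    t, u, rep = _pulse_train(profile)
    xyz = np.empty((len(t), len(JOINT_NAMES), 3))
    sides = ("l", "r")
    for i in range(len(t)):
        side = sides[rep[i] % 2] if rep[i] >= 0 else "l"
        xyz[i] = _pose_at(profile.exercise_name, float(u[i]), side, p, geom)
    rng = np.random.default_rng(profile.seed)
    if profile.noise_sd > 0:
        xyz = xyz + rng.normal(0.0, profile.noise_sd, xyz.shape)
    missing = np.zeros((len(t), len(JOINT_NAMES)), dtype=bool)
    if profile.dropout_rate > 0:
        drop = rng.random(len(t)) < profile.dropout_rate
        missing[drop] = True
        xyz[drop] = np.nan
    return SkeletonSequence(times=t, xyz=xyz, missing=missing)


# --------------------------------------------------------------------------
# ATD session series
# --------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Distributional recipe for a synthetic alternating-treatments series.

    ``feedback_delta = 0`` with ``miscount_sd_no_feedback = 0`` makes the two
    conditions exchangeable (the null for randomization-test calibration).
    """

    baseline_adherence: float = 0.8
    feedback_delta: float = 0.2
    session_sd: float = 0.15
    trend_per_session: float = 0.0
    miscount_sd_no_feedback: float = 0.0
    fidelity_fraction: float = 0.45
    fidelity_sd: float = 0.08
    rating_mean: float = 3.5
    rating_shift_feedback: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_sd < 0 or self.miscount_sd_no_feedback < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_atd_sessions(spec: EffectSpec, schedule: list[str],
                          phase: list[str] | None = None) -> list[SessionRecord]:
    """One :class:`SessionRecord` per schedule entry.

    Feedback sessions have mean adherence ``baseline + delta``; no-feedback
    sessions get extra self-counting noise (``miscount_sd_no_feedback``).
    Adherence is clipped at zero, fidelity at [0, adherence].
    """
    if not schedule:
        raise ScheduleError("schedule is empty")
    bad = set(schedule) - set(CONDITIONS)
    if bad:
        raise ScheduleError(f"unknown condition labels {sorted(bad)}")
    rng = np.random.default_rng(spec.seed)
    records = []
    for i, cond in enumerate(schedule):
        adh = (spec.baseline_adherence + spec.trend_per_session * i
               + rng.normal(0.0, spec.session_sd))
        if cond == "feedback":
            adh += spec.feedback_delta
        else:
            adh += rng.normal(0.0, spec.miscount_sd_no_feedback)
        adh = max(adh, 0.0)
        q = np.clip(rng.normal(spec.fidelity_fraction, spec.fidelity_sd), 0.0, 1.0)
        fid = adh * q
        shift = spec.rating_shift_feedback if cond == "feedback" else 0.0
        fun = int(np.clip(np.round(rng.normal(spec.rating_mean + shift, 1.0)), 1, 5))
        helpful = int(np.clip(np.round(rng.normal(spec.rating_mean + shift, 1.0)), 1, 5))
        records.append(SessionRecord(
            session_index=i + 1,
            condition=cond,
            adherence=float(adh),
            fidelity=float(fid),
            fun_rating=fun,
            helpful_rating=helpful,
            phase=phase[i] if phase else "comparison",
        ))
    return records


# --------------------------------------------------------------------------
# Rater count tables
# --------------------------------------------------------------------------

def simulate_rater_counts(n_videos: int, true_counts, rater_sd: float,
                          system_bias: float, system_sd: float,
                          seed: int = 0):
    """Paired integer manual/system repetition counts per video.

    manual = true + rater noise; system = true + bias + system noise; both
    rounded and clipped at zero. Returns an :class:`~exengage.agreement.AgreementTable`.
    """
    from .agreement import AgreementTable  # local import avoids a cycle

    if n_videos < 0:
        raise ValueError("n_videos must be >= 0")
    true = np.asarray(true_counts, dtype=float)
    if true.shape[0] != n_videos:
        raise ValueError("n_videos must equal len(true_counts)")
    rng = np.random.default_rng(seed)
    manual = np.clip(np.round(true + rng.normal(0, rater_sd, n_videos)), 0, None)
    system = np.clip(np.round(true + system_bias + rng.normal(0, system_sd, n_videos)),
                     0, None)
    return AgreementTable(
        video_id=[f"v{i:03d}" for i in range(n_videos)],
        manual=manual.astype(int),
        system=system.astype(int),
    )
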