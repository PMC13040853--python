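"""Engagement outcomes: adherence, fidelity, star ratings, session summaries.

Exercise *adherence* is attempted repetitions (or attempt duration for timed
exercises) divided by the prescription; *fidelity* is high-quality
repetitions (or best held time) divided by the prescription. Both are
proportions that may exceed 1.0 when a child does more than prescribed.
The in-game three-star rating reflects the fraction of repetitions performed
with appropriate form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .kinematics import ExerciseDefinition, HoldResult, RepetitionEvent

#: Extra attempts allowed beyond the prescription in the feedback condition
#: before the game advances to the next exercise.
FEEDBACK_EXTRA_ATTEMPTS: int = 3

#: Star-rating band edges on the quality fraction.
STAR_LOW: float = 0.50
STAR_HIGH: float = 0.75

CONDITIONS = ("feedback", "no_feedback")


@dataclass
class ExerciseOutcome:
    """Counts/times for one exercise within one session (across sets)."""

    name: str
    attempted: float  # count, or summed attempt duration (s) for timed
    quality: float    # count, or best held time (s) for timed
    prescribed: float  # count, or prescribed time (s), totalled across sets
    mode: str = "reps"
    stars: int | None = None


@dataclass
class SessionRecord:
    """One exercise session: condition, per-exercise outcomes, engagement."""

    session_index: int
    condition: str
    exercises: dict[str, ExerciseOutcome] = field(default_factory=dict)
    adherence: float | None = None
    fidelity: float | None = None
    fun_rating: int | None = None
    helpful_rating: int | None = None
    active_play_time_min: float | None = None
    phase: str = "comparison"  # "comparison" | "best_alone"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for r in (self.fun_rating, self.helpful_rating):
            if r is not None and r not in range(1, 6):
                raise ValueError("smiley ratings are integers 1..5")


def adherence(attempted: float, prescribed: float, exercise: str = "") -> float:
    """Attempted reps (or seconds) over prescribed; may exceed 1.0."""
    if prescribed <= 0:
        raise ZeroDivisionError(
            f"prescription must be positive ({exercise or 'exercise'})")
    if attempted < 0:
        raise ValueError("attempted must be >= 0")
    return attempted / prescribed


def fidelity(quality: float, prescribed: float, attempted: float | None = None,
             exercise: str = "") -> float:
    """High-quality reps (or best held time) over prescribed; may exceed 1.0."""
    if prescribed <= 0:
        raise ZeroDivisionError(
            f"prescription must be positive ({exercise or 'exercise'})")
    if attempted is not None and quality > attempted:
        raise ValueError(
            f"quality count {quality} exceeds attempted {attempted} "
            f"({exercise or 'exercise'})")
    return quality / prescribed


def star_rating(quality_fraction: float) -> int:
    """Three-star movement-quality rating.

    Less than 50% of repetitions with appropriate form earns 1 star (the
    minimum, always awarded), 50–75% earns 2 stars, and more than 75% earns
    3 stars. The boundaries 0.50 and 0.75 fall in the 2-star band by the
    literal reading of the rule.
    """
    if quality_fraction < 0:
        raise ValueError("quality fraction must be >= 0")
    if quality_fraction < STAR_LOW:
        return 1
    if quality_fraction <= STAR_HIGH:
        return 2
    return 3


def _count_events(events: list[RepetitionEvent]) -> tuple[float, float]:
    attempted = sum(1 for e in events if e.attempt)
    quality = sum(1 for e in events if e.quality)
    return float(attempted), float(quality)


def summarize_session(
    observations: dict[str, list[RepetitionEvent] | HoldResult | ExerciseOutcome],
    definitions: dict[str, ExerciseDefinition],
    condition: str,
    session_index: int = 0,
    feedback_caps: bool = True,
    aggregate: str = "mean",
    fun_rating: int | None = None,
    helpful_rating: int | None = None,
    phase: str = "comparison",
) -> SessionRecord:
    """Aggregate detected events into a session record.

    ``observations`` maps exercise name to detected events (repetition
    exercises), a :class:`HoldResult` (timed exercises), or a pre-counted
    :class:`ExerciseOutcome`. In the feedback condition with caps enabled,
    attempted counts are capped at prescribed + 3 per exercise, mirroring the
    in-game limit; the cap never applies to self-counted no-feedback
    sessions. Session adherence/fidelity are the unweighted mean of the
    per-exercise proportions (``aggregate="mean"``) or the ratio of summed
    counts (``aggregate="pooled"``).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    outcomes: dict[str, ExerciseOutcome] = {}
    for name, obs in observations.items():
        if name not in definitions:
            raise ConfigurationError(f"no definition for exercise {name!r}")
        ex = definitions[name]
        prescribed = ex.prescribed_total
        if isinstance(obs, ExerciseOutcome):
            out = obs
        elif isinstance(obs, HoldResult):
            # adherence uses summed attempt durations capped at the
            # prescription per set; fidelity uses the best single hold
            dur = sum(min(t, ex.prescribed_time_s) for t in obs.attempt_times)
            dur = min(dur, prescribed)
            out = ExerciseOutcome(name, attempted=dur, quality=obs.best_time,
                                  prescribed=prescribed, mode="timed")
        else:
            attempted, quality = _count_events(obs)
            out = ExerciseOutcome(name, attempted=attempted, quality=quality,
                                  prescribed=prescribed, mode="reps")
        if (feedback_caps and condition == "feedback" and out.mode == "reps"):
            out.attempted = min(out.attempted, prescribed + FEEDBACK_EXTRA_ATTEMPTS)
        if condition == "feedback" and out.attempted > 0:
            out.stars = star_rating(out.quality / out.attempted)
        outcomes[name] = out

    adh = [adherence(o.attempted, o.prescribed, o.name) for o in outcomes.values()]
    fid = [fidelity(o.quality, o.prescribed, exercise=o.name) for o in outcomes.values()]
    if aggregate == "mean":
        session_adh = sum(adh) / len(adh) if adh else None
        session_fid = sum(fid) / len(fid) if fid else None
    elif aggregate == "pooled":
        tot_presc = sum(o.prescribed for o in outcomes.values())
        session_adh = sum(o.attempted for o in outcomes.values()) / tot_presc
        session_fid = sum(o.quality for o in outcomes.values()) / tot_presc
    else:
        raise ConfigurationError(f"unknown aggregate mode {aggregate!r}")

    return SessionRecord(
        session_index=session_index,
        condition=condition,
        exercises=outcomes,
        adherence=session_adh,
        fidelity=session_fid,
        fun_rating=fun_rating,
        helpful_rating=helpful_rating,
        phase=phase,
    )
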