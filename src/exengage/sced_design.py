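"""Restricted randomization schedules for alternating-treatments designs.

An alternating-treatments design (ATD) compares two conditions within one
participant by alternating them across sessions. To protect internal
validity the schedule is drawn from a *restricted* randomization space: no
more than ``max_run`` consecutive sessions of the same condition (default 2),
optionally with (near-)balanced condition counts. The same space later
defines the null distribution of the single-case randomization test.

The module also applies the best-alone selection rule used at the end of the
comparison phase: the condition with at least 90% non-overlap of the
adherence data paths is declared superior; failing that, the condition with
the higher mean adherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .engagement import CONDITIONS

#: Largest n_sessions for exhaustive enumeration.
ENUMERATION_CAP: int = 24

#: PND at or above this percentage identifies the superior condition.
PND_SUPERIORITY_THRESHOLD: float = 90.0

_LETTER = {"feedback": "F", "no_feedback": "N"}
_CONDITION = {v: k for k, v in _LETTER.items()}


@dataclass(frozen=True)
class ScheduleSpace:
    """Exhaustive set of admissible condition sequences."""

    n_sessions: int
    max_run: int
    balance: bool
    schedules: tuple[tuple[str, ...], ...]

    def __contains__(self, schedule) -> bool:
        return tuple(schedule) in set(self.schedules)

    def __len__(self) -> int:
        return len(self.schedules)


def schedule_to_string(schedule) -> str:
    """Serialize a schedule as a single-line condition string, e.g. FNFFNN."""
    return "".join(_LETTER[c] for c in schedule)


def schedule_from_string(s: str) -> tuple[str, ...]:
    try:
        return tuple(_CONDITION[ch] for ch in s.strip().upper())
    except KeyError as exc:
        raise ConfigurationError(f"unknown condition letter {exc}") from exc


def enumerate_schedules(n_sessions: int, max_run: int = 2,
                        balance: bool = True) -> ScheduleSpace:
    """Enumerate every admissible schedule, in deterministic order.

    A schedule is admissible when no run of identical conditions exceeds
    ``max_run`` and, if ``balance``, the two condition counts differ by at
    most one (equal when ``n_sessions`` is even).
    """
    if n_sessions < 1 or max_run < 1:
        raise ValueError("n_sessions and max_run must be >= 1")
    if n_sessions > ENUMERATION_CAP:
        raise ValueError(
            f"n_sessions={n_sessions} exceeds the enumeration cap "
            f"({ENUMERATION_CAP}); draw schedules by rejection sampling instead")
    out: list[tuple[str, ...]] = []

    def extend(prefix: list[str], run: int, n_f: int) -> None:
        k = len(prefix)
        if k == n_sessions:
            if balance and abs(2 * n_f - n_sessions) > 1:
                return
            out.append(tuple(prefix))
            return
        if balance:
            # prune branches that can no longer balance
            remaining = n_sessions - k
            need_f = (n_sessions - 1) // 2 - n_f
            if need_f > remaining or (n_f - (n_sessions + 1) // 2) > 0:
                return
        for cond in CONDITIONS:  # 'feedback' < 'no_feedback': lexicographic order
            new_run = run + 1 if prefix and prefix[-1] == cond else 1
            if new_run > max_run:
                continue
            prefix.append(cond)
            extend(prefix, new_run, n_f + (cond == "feedback"))
            prefix.pop()

    extend([], 0, 0)
    return ScheduleSpace(n_sessions=n_sessions, max_run=max_run,
                         balance=balance, schedules=tuple(out))


def draw_schedule(space: ScheduleSpace, seed: int) -> tuple[str, ...]:
    """Uniform, seed-reproducible draw from a schedule space."""
    if len(space) == 0:
        raise ConfigurationError("schedule space is empty")
    rng = np.random.default_rng(seed)
    return space.schedules[int(rng.integers(len(space)))]


@dataclass
class BestAloneDecision:
    """Outcome of the best-alone selection rule, with its rationale."""

    condition: str | None
    rule: str  # "pnd" | "mean" | "undetermined"
    pnd_feedback: float
    pnd_no_feedback: float
    mean_feedback: float
    mean_no_feedback: float
    detail: str = ""


def select_best_alone(series) -> BestAloneDecision:
    """Pick the condition to continue alone after the comparison phase.

    A condition whose adherence data path shows >= 90% non-overlap (PND) is
    superior; otherwise the condition with the higher mean adherence wins.
    An exact mean tie is surfaced as ``undetermined`` rather than broken
    silently.
    """
    from .sced_stats import pnd  # circular at import time only

    conds = np.asarray(series.conditions)
    values = np.asarray(series.values, dtype=float)
    means = {}
    for cond in CONDITIONS:
        sel = conds == cond
        if not sel.any():
            raise InsufficientDataError(f"no sessions in condition {cond!r}")
        means[cond] = float(values[sel].mean())

    pnd_f = pnd(series, favoured="feedback")
    pnd_n = pnd(series, favoured="no_feedback")
    common = dict(pnd_feedback=pnd_f, pnd_no_feedback=pnd_n,
                  mean_feedback=means["feedback"],
                  mean_no_feedback=means["no_feedback"])
    for cond, p in (("feedback", pnd_f), ("no_feedback", pnd_n)):
        if p >= PND_SUPERIORITY_THRESHOLD:
            return BestAloneDecision(
                condition=cond, rule="pnd",
                detail=f"PND {p:.1f}% >= {PND_SUPERIORITY_THRESHOLD:.0f}% "
                       f"favouring {cond}", **common)
    if means["feedback"] == means["no_feedback"]:
        return BestAloneDecision(
            condition=None, rule="undetermined",
            detail="exact mean-adherence tie; explicit override required",
            **common)
    winner = max(means, key=means.get)
    return BestAloneDecision(
        condition=winner, rule="mean",
        detail=(f"PND below threshold; mean adherence "
                f"{means[winner]:.3f} favours {winner}"), **common)
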