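"""Quantitative single-case analyses for alternating-treatments series.

Implements the analysis battery for a two-condition (feedback vs
no-feedback) alternating-treatments design:

* percentage of non-overlapping data (PND) over adjacent between-condition
  comparisons,
* a quantified visual summary (level, trend, variability),
* the single-case randomization test (SCRT), whose null distribution
  re-assigns the observed outcomes across every schedule admissible under
  the design's restricted randomization scheme — never unrestricted
  shuffles,
* Fisher-Pitman permutation test (unpaired) and Wilcoxon signed-rank test
  with Pratt's treatment of zero differences (paired), both one-tailed with
  ties counted as extreme and exhaustive enumeration whenever feasible,
* the two-sample JZS Bayes-factor t-test (Cauchy prior on effect size,
  scale r = sqrt(2)/2), computed by numerical integration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special, stats

from .engagement import CONDITIONS, SessionRecord
from .errors import (
    DegenerateDataError,
    DesignViolationError,
    InsufficientDataError,
    PairingError,
)
from .sced_design import ScheduleSpace

#: Default Monte-Carlo resampling budget; enumeration is used below it.
DEFAULT_N_MC: int = 10_000

#: Default significance level for the battery.
ALPHA: float = 0.05

#: JZS Cauchy prior scale on the standardized effect size.
JZS_PRIOR_SCALE: float = np.sqrt(2) / 2

#: Visual-summary default bands (all configurable per call).
TREND_ZERO_SLOPE: float = 0.01    # |slope|/session below this: zero-celerating
TREND_STEEP_SLOPE: float = 0.05   # above this: steep
CV_STABLE: float = 0.10           # coefficient of variation bands
CV_SOMEWHAT: float = 0.25

LEVELS = ("low", "moderate", "high")
TRENDS = ("zero-celerating", "gradual accelerating", "gradual decelerating",
          "steep accelerating", "steep decelerating")
VARIABILITIES = ("stable", "somewhat variable", "highly variable")


@dataclass
class ATDSeries:
    """Ordered sessions of an alternating-treatments series.

    Wraps :class:`~exengage.engagement.SessionRecord` objects and exposes the
    outcome named by ``outcome_name`` ("adherence", "fidelity", "fun",
    "helpful") as a numeric vector for analysis.
    """

    records: list[SessionRecord]
    outcome_name: str = "adherence"

    _FIELD = {"adherence": "adherence", "fidelity": "fidelity",
              "fun": "fun_rating", "helpful": "helpful_rating"}

    def __post_init__(self) -> None:
        if self.outcome_name not in self._FIELD:
            raise ValueError(f"unknown outcome {self.outcome_name!r}")
        idx = [r.session_index for r in self.records]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("session_index must be strictly increasing")
        for r in self.records:
            if r.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {r.condition!r}")

    @property
    def conditions(self) -> np.ndarray:
        return np.array([r.condition for r in self.records])

    @property
    def values(self) -> np.ndarray:
        f = self._FIELD[self.outcome_name]
        return np.array([getattr(r, f) for r in self.records], dtype=float)

    @property
    def session_index(self) -> np.ndarray:
        return np.array([r.session_index for r in self.records])

    def with_outcome(self, name: str) -> "ATDSeries":
        return ATDSeries(self.records, outcome_name=name)

    def comparison_phase(self) -> "ATDSeries":
        return ATDSeries([r for r in self.records if r.phase == "comparison"],
                         outcome_name=self.outcome_name)

    def condition_values(self, condition: str) -> np.ndarray:
        v, c = self.values, self.conditions
        return v[c == condition]

    @staticmethod
    def from_values(conditions, values, outcome_name: str = "adherence",
                    phase=None) -> "ATDSeries":
        """Build a series directly from condition labels and outcome values."""
        records = []
        for i, (c, v) in enumerate(zip(conditions, values)):
            rec = SessionRecord(session_index=i + 1, condition=c,
                                phase=(phase[i] if phase else "comparison"))
            if outcome_name in ("fun", "helpful"):
                setattr(rec, ATDSeries._FIELD[outcome_name], int(v))
            else:
                setattr(rec, ATDSeries._FIELD[outcome_name], float(v))
            records.append(rec)
        return ATDSeries(records, outcome_name=outcome_name)


@dataclass
class TestResult:
    """Result of one hypothesis test in the battery."""

    method: str
    statistic: float
    p_value: float | None = None
    bayes_factor: float | None = None
    n_resamples: int = 0
    exhaustive: bool = False
    alternative: str = "greater"
    seed: int | None = None
    alpha: float = ALPHA

    @property
    def significant(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value <= self.alpha


@dataclass
class VisualSummary:
    """Quantified visual-analysis labels for one outcome series."""

    level: str
    trend: str
    variability: str
    mean: float
    slope: float
    cv: float
    pnd: float | None = None


# --------------------------------------------------------------------------
# Percentage of non-overlapping data
# --------------------------------------------------------------------------

def _adjacent_comparisons(conditions: np.ndarray) -> list[tuple[int, int]]:
    """Pair each condition transition in session order.

    One comparison per adjacent transition, each session used at most once:
    scanning chronologically, whenever two consecutive unused sessions carry
    different conditions they form a comparison.
    """
    pairs: list[tuple[int, int]] = []
    used = np.zeros(len(conditions), dtype=bool)
    for i in range(1, len(conditions)):
        if used[i - 1] or used[i]:
            continue
        if conditions[i] != conditions[i - 1]:
            pairs.append((i - 1, i))
            used[i - 1] = used[i] = True
    return pairs


def pnd(series: ATDSeries, favoured: str = "feedback") -> float:
    """Percentage of non-overlapping data over between-session comparisons.

    100 x (comparisons where the favoured condition's value strictly exceeds
    the other's) / (number of comparisons). Exact ties count as overlap.
    """
    if favoured not in CONDITIONS:
        raise ValueError(f"unknown condition {favoured!r}")
    conds, values = series.conditions, series.values
    pairs = _adjacent_comparisons(conds)
    if not pairs:
        raise InsufficientDataError("no between-condition comparisons in series")
    wins = 0
    for a, b in pairs:
        fav, other = (a, b) if conds[a] == favoured else (b, a)
        wins += values[fav] > values[other]
    return 100.0 * wins / len(pairs)


# --------------------------------------------------------------------------
# Visual summary
# --------------------------------------------------------------------------

def visual_summary(series: ATDSeries, scale: tuple[float, float],
                   trend_zero: float = TREND_ZERO_SLOPE,
                   trend_steep: float = TREND_STEEP_SLOPE,
                   cv_stable: float = CV_STABLE,
                   cv_somewhat: float = CV_SOMEWHAT) -> VisualSummary:
    """Quantify level, trend and variability of an outcome series.

    Level compares the mean with tertiles of the outcome scale; trend bands
    the least-squares slope per session; variability bands the coefficient
    of variation. Thresholds are configurable; the defaults are the
    package's own operationalization of the conventional qualitative labels.
    """
    lo, hi = scale
    if hi <= lo:
        raise ValueError("outcome scale range must be positive")
    v = series.values
    if len(v) < 2:
        raise InsufficientDataError("need >= 2 sessions for a visual summary")
    mean = float(v.mean())
    third = (hi - lo) / 3
    level = LEVELS[min(2, int((mean - lo) // third))] if mean < hi else "high"

    x = np.arange(len(v), dtype=float)
    slope = float(np.polyfit(x, v, 1)[0])
    if abs(slope) < trend_zero:
        trend = "zero-celerating"
    else:
        mag = "gradual" if abs(slope) < trend_steep else "steep"
        direction = "accelerating" if slope > 0 else "decelerating"
        trend = f"{mag} {direction}"

    cv = float(v.std(ddof=1) / abs(mean)) if mean != 0 else np.inf
    if cv < cv_stable:
        variability = "stable"
    elif cv < cv_somewhat:
        variability = "somewhat variable"
    else:
        variability = "highly variable"

    try:
        overlap = pnd(series)
    except InsufficientDataError:
        overlap = None
    return VisualSummary(level=level, trend=trend, variability=variability,
                         mean=mean, slope=slope, cv=cv, pnd=overlap)


# --------------------------------------------------------------------------
# Permutation machinery
# --------------------------------------------------------------------------

def _one_tailed_p(null: np.ndarray, observed: float, alternative: str) -> float:
    """Proportion of null statistics at least as extreme as observed.

    Ties count as extreme (conservative); the observed assignment is always
    a member of the null set, so p > 0.
    """
    tol = 1e-12
    if alternative == "greater":
        extreme = null >= observed - tol
    elif alternative == "less":
        extreme = null <= observed + tol
    else:
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    return float(np.mean(extreme))


def scrt(series: ATDSeries, space: ScheduleSpace,
         alternative: str = "greater", n_mc: int = DEFAULT_N_MC,
         seed: int = 0) -> TestResult:
    """Single-case randomization test for an alternating-treatments series.

    The statistic is the difference in condition means (feedback minus
    no-feedback) under the observed schedule. The null distribution
    recomputes it under every schedule admissible in the restricted
    randomization space — exhaustively when the space has at most ``n_mc``
    members, otherwise over a Monte-Carlo sample that always includes the
    observed schedule.
    """
    values = series.values
    observed = tuple(series.conditions)
    if observed not in space:
        raise DesignViolationError(
            "observed schedule is not a member of the randomization space")
    schedules = space.schedules
    exhaustive = len(schedules) <= n_mc
    if not exhaustive:
        rng = np.random.default_rng(seed)
        pick = rng.integers(0, len(schedules), size=n_mc - 1)
        schedules = tuple(schedules[i] for i in pick) + (observed,)
    mask = np.array([[c == "feedback" for c in s] for s in schedules])
    n_f = mask.sum(axis=1)
    n_n = mask.shape[1] - n_f
    sums = mask @ values
    null = sums / n_f - (values.sum() - sums) / n_n

    obs_mask = np.array([c == "feedback" for c in observed])
    stat = float(values[obs_mask].mean() - values[~obs_mask].mean())
    p = _one_tailed_p(null, stat, alternative)
    return TestResult(method="scrt", statistic=stat, p_value=p,
                      n_resamples=len(schedules), exhaustive=exhaustive,
                      alternative=alternative, seed=seed)


def fisher_pitman(a, b, alternative: str = "greater",
                  n_mc: int = DEFAULT_N_MC, seed: int = 0) -> TestResult:
    """One-tailed Fisher-Pitman permutation test for unpaired samples.

    Statistic: mean(a) - mean(b). The null reassigns group labels over all
    C(n, n_a) splits when that count is within ``n_mc``, otherwise over a
    Monte-Carlo sample including the observed labelling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    stat = float(a.mean() - b.mean())

    n_splits = special.comb(n, na, exact=True)
    if n_splits <= n_mc:
        idx = np.fromiter(
            (i for comb in itertools.combinations(range(n), na) for i in comb),
            dtype=np.intp, count=n_splits * na).reshape(n_splits, na)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_mc - 1, n)), axis=1)[:, :na]
        idx = np.vstack([idx, np.arange(na)])  # observed labelling included
        exhaustive = False
    sums_a = pooled[idx].sum(axis=1)
    null = sums_a / na - (pooled.sum() - sums_a) / (n - na)
    p = _one_tailed_p(null, stat, alternative)
    return TestResult(method="fisher_pitman", statistic=stat, p_value=p,
                      n_resamples=idx.shape[0], exhaustive=exhaustive,
                      alternative=alternative, seed=seed)


def wilcoxon_pratt(a, b, alternative: str = "greater",
                   n_mc: int = DEFAULT_N_MC, seed: int = 0) -> TestResult:
    """One-tailed Wilcoxon signed-rank test with Pratt zero handling.

    Differences d = a - b are ranked by |d| *including* zeros; zero
    differences are then discarded (Pratt) and the statistic is the sum of
    ranks of positive differences. The null flips the signs of the non-zero
    differences — exhaustively over all 2^m patterns when feasible. With all
    differences zero the test is degenerate and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise PairingError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise InsufficientDataError("need at least one pair")
    d = a - b
    ranks = stats.rankdata(np.abs(d))          # zeros ranked with all |d| ...
    keep = d != 0
    ranks, signs = ranks[keep], np.sign(d[keep])  # ... then discarded (Pratt)
    m = int(keep.sum())
    stat = float(np.median(d))
    w_obs = float(ranks[signs > 0].sum())
    if m == 0:
        return TestResult(method="wilcoxon_pratt", statistic=stat, p_value=1.0,
                          n_resamples=1, exhaustive=True,
                          alternative=alternative, seed=seed)
    if 2 ** m <= n_mc:
        bits = (np.arange(2 ** m)[:, None] >> np.arange(m)) & 1
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        bits = rng.integers(0, 2, size=(n_mc - 1, m))
        bits = np.vstack([bits, (signs > 0).astype(int)])  # observed pattern
        exhaustive = False
    null = (bits * ranks).sum(axis=1).astype(float)
    # alternative 'greater' (a > b) means large positive-rank sums are extreme
    p = _one_tailed_p(null, w_obs, alternative)
    return TestResult(method="wilcoxon_pratt", statistic=stat, p_value=p,
                      n_resamples=bits.shape[0], exhaustive=exhaustive,
                      alternative=alternative, seed=seed)


# --------------------------------------------------------------------------
# JZS Bayes factor
# --------------------------------------------------------------------------

def bayes_factor_t(a, b, prior_scale: float = JZS_PRIOR_SCALE) -> TestResult:
    """Two-sample JZS Bayes factor BF10 by numerical integration.

    The alternative places a Cauchy prior with scale ``prior_scale`` on the
    standardized effect size (equivalently, an inverse-gamma(1/2, r^2/2)
    prior on g in the g-prior formulation). BF10 below 1 is evidence for the
    null of no mean difference. Two-sided, matching the field-standard
    default.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    na, nb = a.size, b.size
    nu = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / nu
    if sp2 == 0:
        raise DegenerateDataError("zero pooled variance")
    n_eff = na * nb / (na + nb)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 / n_eff)

    r2 = prior_scale ** 2

    def integrand(g: float) -> float:
        # marginal likelihood ratio term x inverse-gamma(1/2, r^2/2) density
        like = (1 + n_eff * g) ** -0.5 * (
            1 + t ** 2 / ((1 + n_eff * g) * nu)) ** (-(nu + 1) / 2)
        prior = (np.sqrt(r2 / (2 * np.pi)) * g ** -1.5 * np.exp(-r2 / (2 * g)))
        return like * prior

    numerator, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    denominator = (1 + t ** 2 / nu) ** (-(nu + 1) / 2)
    bf10 = float(numerator / denominator)
    return TestResult(method="jzs_bayes_t", statistic=float(a.mean() - b.mean()),
                      bayes_factor=bf10, alternative="two-sided")


def interpret_bayes_factor(bf10: float) -> str:
    """Conventional qualitative reading of BF10 (Jeffreys-style bands)."""
    if bf10 <= 0:
        raise ValueError("Bayes factor must be positive")
    for cut, label in ((1 / 10, "strong evidence for the null"),
                       (1 / 3, "moderate evidence for the null"),
                       (1, "anecdotal evidence for the null"),
                       (3, "anecdotal evidence for a difference"),
                       (10, "moderate evidence for a difference")):
        if bf10 < cut:
            return label
    return "strong evidence for a difference"
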