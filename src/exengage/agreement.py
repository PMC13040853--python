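"""Manual-vs-system and rater-vs-rater agreement statistics.

Three complementary views of measurement agreement:

* **WMRE** — weighted mean relative error of system repetition counts
  against manual ground truth, aggregated as the ratio of sums
  (equivalently, per-video relative errors weighted by manual counts).
  Below 25% is considered acceptable: a larger counting error would move a
  child into a different three-star movement-quality band regardless of
  their actual performance.
* **ICC(2,1)** — two-way random-effects, absolute-agreement, single-measure
  intraclass correlation with exact F-based 95% confidence bounds,
  generalizing reliability to the population of raters. Graded poor /
  moderate / good / excellent at 0.5 / 0.75 / 0.9.
* **Bland-Altman** — bias (mean difference) and 95% limits of agreement,
  with the per-row (mean, difference) pairs exposed for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError

#: WMRE acceptability threshold, percent.
WMRE_ACCEPTABLE_PCT: float = 25.0

#: ICC grade band edges (poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent).
ICC_MODERATE: float = 0.50
ICC_GOOD: float = 0.75
ICC_EXCELLENT: float = 0.90


@dataclass
class AgreementTable:
    """Paired manual/system counts (or times) per video, manual = ground truth."""

    video_id: list[str]
    manual: np.ndarray
    system: np.ndarray
    rater2: np.ndarray | None = None  # optional second manual rater

    def __post_init__(self) -> None:
        self.manual = np.asarray(self.manual, dtype=float)
        self.system = np.asarray(self.system, dtype=float)
        if self.rater2 is not None:
            self.rater2 = np.asarray(self.rater2, dtype=float)
        n = len(self.video_id)
        if self.manual.shape != (n,) or self.system.shape != (n,):
            raise ValueError("column lengths disagree")
        if n < 1:
            raise ValueError("agreement table needs at least one row")
        if np.any(self.manual < 0) or np.any(self.system < 0):
            raise ValueError("counts must be >= 0")


@dataclass
class AgreementResult:
    """Container filled incrementally by the agreement operations."""

    wmre: float | None = None
    acceptable: bool | None = None
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    icc_grade: str | None = None
    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    pairs: list[tuple[float, float]] = field(default_factory=list)


def wmre(table: AgreementTable, per_video: bool = False) -> AgreementResult:
    """Weighted mean relative error of system counts vs manual ground truth.

    Default aggregation is the ratio of sums,
    ``100 * sum|system - manual| / sum(manual)``; a system that records
    nothing scores exactly 100%. ``per_video=True`` switches to the
    unweighted mean of per-video relative errors (videos with zero manual
    count are then excluded).
    """
    man, sys_ = table.manual, table.system
    if man.sum() <= 0:
        raise DegenerateDataError("all manual counts are zero: WMRE undefined")
    if per_video:
        keep = man > 0
        value = 100.0 * float(np.mean(np.abs(sys_[keep] - man[keep]) / man[keep]))
    else:
        value = 100.0 * float(np.abs(sys_ - man).sum() / man.sum())
    return AgreementResult(wmre=value, acceptable=value < WMRE_ACCEPTABLE_PCT)


def icc_grade(icc: float) -> str:
    if icc >= ICC_EXCELLENT:
        return "excellent"
    if icc >= ICC_GOOD:
        return "good"
    if icc >= ICC_MODERATE:
        return "moderate"
    return "poor"


def icc_2_1(ratings: np.ndarray, confidence: float = 0.95) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an n_subjects x k_raters table with no missing cells.
    The estimate comes from the mean squares of the two-way decomposition;
    the confidence interval uses the exact F-distribution bounds.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters table")
    n, k = x.shape
    if n < 3 or k < 2:
        raise InsufficientDataError("need >= 3 subjects and >= 2 raters")
    if np.any(np.isnan(x)):
        raise InsufficientDataError("ratings table contains missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # subjects
    msc = ss_cols / (k - 1)          # raters
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # Exact F-based bounds for ICC(A,1) (two-way random, absolute agreement)
    alpha = 1 - confidence
    if icc >= 1.0 or mse == 0 and msc == 0 and msr == 0:
        lo = hi = icc
    else:
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr)
    return AgreementResult(icc=float(icc), icc_ci=(float(lo), float(hi)),
                           icc_grade=icc_grade(float(icc)))


def bland_altman(table: AgreementTable, z: float = 1.96) -> AgreementResult:
    """Bias and 95% limits of agreement between system and manual counts.

    bias = mean(system - manual); limits = bias +/- 1.96 x SD(differences)
    (sample SD). Per-row (mean, difference) pairs are returned for plotting.
    """
    if len(table.video_id) < 2:
        raise InsufficientDataError("Bland-Altman needs >= 2 rows")
    d = table.system - table.manual
    m = (table.system + table.manual) / 2
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias, loa_low=bias - z * sd, loa_high=bias + z * sd,
        pairs=list(zip(m.tolist(), d.tolist())))
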