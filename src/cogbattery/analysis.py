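"""Evaluation statistics: usability factor scoring, correlations, summaries.

Covers the three analyses run on battery studies:

* **PSSUQ usability scoring** — the Post-Study System Usability
  Questionnaire has 19 items rated 1 (strongly disagree) to 5 (strongly
  agree). Factors are arithmetic means over item blocks, using the
  instrument's published mapping: system usefulness = items 1-8,
  information quality = items 9-15, interface quality = items 16-18,
  overall = items 1-19. Missing items are skipped (mean over present
  items); a factor with no present items is undefined.
* **Concurrent validity** — Pearson two-tailed correlation between a new
  instrument's scores and an established instrument's scores on the same
  subjects, one row per matched subtest pair plus totals, flagged at the
  .05 significance level. Rows with missing data are dropped pairwise and
  the per-row n is reported.
* **Score summaries** — five-number (boxplot) summaries per subtest using
  Tukey hinges for the quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import TASK_IDS, ScoreReport

__all__ = [
    "PSSUQ_FACTOR_ITEMS",
    "AnalysisError",
    "UndefinedFactorError",
    "UndefinedCorrelationError",
    "EmptyReportError",
    "PSSUQResult",
    "CorrelationResult",
    "pssuq_scores",
    "pearson_r",
    "validity_report",
    "score_summary",
    "tukey_five_number",
]


class AnalysisError(ValueError):
    pass


class UndefinedFactorError(AnalysisError):
    """A usability factor has no present constituent items."""


class UndefinedCorrelationError(AnalysisError):
    """Correlation undefined (zero variance or too few observations)."""


class EmptyReportError(AnalysisError):
    """No pair in the table has enough complete observations."""


#: Published item-factor mapping (1-based item numbers). Loadable configs may
#: substitute alternative mappings via the ``factors`` argument of
#: :func:`pssuq_scores`.
PSSUQ_FACTOR_ITEMS: dict[str, tuple[int, ...]] = {
    "system_usefulness": tuple(range(1, 9)),
    "information_quality": tuple(range(9, 16)),
    "interface_quality": tuple(range(16, 19)),
    "overall": tuple(range(1, 20)),
}

_N_PSSUQ_ITEMS = 19


@dataclass(frozen=True)
class PSSUQResult:
    overall: float
    system_usefulness: float
    information_quality: float
    interface_quality: float

    def __post_init__(self) -> None:
        for name in ("overall", "system_usefulness", "information_quality", "interface_quality"):
            value = getattr(self, name)
            if not 1.0 <= value <= 5.0:
                raise AnalysisError(f"factor {name}={value} outside [1, 5]")


def pssuq_scores(
    response: Sequence[int | None],
    factors: Mapping[str, Sequence[int]] | None = None,
) -> PSSUQResult:
    """Score one questionnaire response into its four usability factors.

    ``response`` holds the 19 item ratings in order; ``None`` marks a
    missing item. Each factor is the mean of its present items.
    """
    factors = dict(factors) if factors is not None else PSSUQ_FACTOR_ITEMS
    if len(response) != _N_PSSUQ_ITEMS:
        raise AnalysisError(f"expected {_N_PSSUQ_ITEMS} item ratings, got {len(response)}")
    for i, rating in enumerate(response, start=1):
        if rating is not None and rating not in (1, 2, 3, 4, 5):
            raise AnalysisError(f"item_{i} rating {rating!r} not in 1..5")
    means: dict[str, float] = {}
    for name, items in factors.items():
        values = [response[i - 1] for i in items if response[i - 1] is not None]
        if not values:
            raise UndefinedFactorError(f"factor {name!r} has no present items")
        means[name] = float(np.mean(values))
    return PSSUQResult(
        overall=means["overall"],
        system_usefulness=means["system_usefulness"],
        information_quality=means["information_quality"],
        interface_quality=means["interface_quality"],
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise AnalysisError(f"|r|={abs(self.r)} exceeds 1")
        if not 0.0 <= self.p <= 1.0:
            raise AnalysisError(f"p={self.p} outside [0, 1]")

    @property
    def significant(self) -> bool:
        """Two-tailed significance at the .05 level."""
        return self.p < 0.05


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with its two-tailed p-value.

    The p-value comes from the exact t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom.
    Requires n >= 3 and non-degenerate variance on both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError(f"x and y must be equal-length 1-d sequences, got {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError(f"need at least 3 observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    result = stats.pearsonr(x, y)
    return CorrelationResult(r=float(result.statistic), p=float(result.pvalue), n=n)


def validity_report(
    paired_scores: pd.DataFrame,
    pairs: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Correlate matched instrument columns across subjects.

    ``paired_scores`` holds one row per subject; by default every pair of
    columns ``a_<name>``/``b_<name>`` (the layout produced by
    :func:`~cogbattery.simulate.simulate_validity_cohort`) is correlated.
    Rows with missing data are dropped pairwise; pairs left with fewer than
    3 complete observations are omitted. Output columns: ``pair_name``,
    ``n``, ``r``, ``p``, ``significant_at_.05``.
    """
    if pairs is None:
        pairs = {}
        for col in paired_scores.columns:
            if col.startswith("a_"):
                other = "b_" + col[2:]
                if other in paired_scores.columns:
                    pairs[col[2:]] = (col, other)
    if not pairs:
        raise EmptyReportError("no matched column pairs found")
    rows = []
    for name, (col_a, col_b) in pairs.items():
        complete = paired_scores[[col_a, col_b]].dropna()
        if len(complete) < 3:
            continue
        try:
            res = pearson_r(complete[col_a].to_numpy(), complete[col_b].to_numpy())
        except UndefinedCorrelationError:
            continue
        rows.append(
            {
                "pair_name": name,
                "n": res.n,
                "r": res.r,
                "p": res.p,
                "significant_at_.05": res.significant,
            }
        )
    if not rows:
        raise EmptyReportError("no pair has at least 3 complete, non-degenerate observations")
    return pd.DataFrame(rows, columns=["pair_name", "n", "r", "p", "significant_at_.05"])


def tukey_five_number(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) with quartiles computed as Tukey hinges.

    The hinges are the medians of the lower and upper halves of the sorted
    data, each half including the overall median when n is odd.
    """
    data = np.sort(np.asarray(values, dtype=float))
    n = len(data)
    if n == 0:
        raise AnalysisError("five-number summary of an empty collection is undefined")
    median = float(np.median(data))
    half = (n + 1) // 2  # halves share the middle element when n is odd
    lower, upper = data[:half], data[n - half:]
    return (float(data[0]), float(np.median(lower)), median, float(np.median(upper)), float(data[-1]))


def score_summary(
    scores: Iterable[ScoreReport] | pd.DataFrame,
) -> pd.DataFrame:
    """Five-number (boxplot) summaries per subtest and for the total.

    Accepts a collection of score reports or a frame with columns
    ``LL``..``VMT`` and ``total``. Quartiles are Tukey hinges.
    """
    if isinstance(scores, pd.DataFrame):
        frame = scores
    else:
        frame = pd.DataFrame([r.as_dict() for r in scores])
    if frame.empty:
        raise AnalysisError("score summary of an empty collection is undefined")
    rows = []
    for task in (*TASK_IDS, "total"):
        if task not in frame.columns:
            continue
        lo, q1, med, q3, hi = tukey_five_number(frame[task].dropna().to_numpy())
        rows.append({"task": task, "min": lo, "q1": q1, "median": med, "q3": q3, "max": hi})
    return pd.DataFrame(rows, columns=["task", "min", "q1", "median", "q3", "max"])
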