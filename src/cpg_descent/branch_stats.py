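"""Branch counts, calibrated rates, chi-square designs, and the scaling fit.

Rates are expressed as CpG gains per million years: the count of sites
originating on a stem divided by the stem's duration in Myr.  Three
chi-square designs mirror the analysis questions:

* ``even`` — are gains uniform over the eight stems? (df = 7)
* ``subset_vs_background`` — does the flagged subset's branch distribution
  differ from the whole data set's? (df = 7, expected proportional to the
  background)
* ``pairwise`` — which stems differ from which? All 28 stem pairs, df = 1,
  expected either an even split (count mode) or a duration-proportional
  split (rate mode).

All statistics are plain Pearson chi-squares without continuity correction;
an expected cell below 5 raises a warning flag rather than switching method.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import UsageError
from .phylo import BRANCH_NAMES, BranchSegment


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    design: str  # even | subset_vs_background | pairwise_count | pairwise_rate
    low_expected: bool  # any expected cell < 5


def branch_rate(count: int, duration: float) -> float:
    """CpG gains per Myr on one stem; report to 1 decimal in tables."""
    if duration <= 0:
        raise UsageError(f"duration must be positive, got {duration}")
    return count / duration


def rate_table(
    counts: Mapping[str, int], segments: Sequence[BranchSegment]
) -> dict[str, float]:
    return {s.name: branch_rate(counts.get(s.name, 0), s.duration) for s in segments}


def _pearson(observed: np.ndarray, expected: np.ndarray, design: str) -> ChiSquareResult:
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p=float(stats.chi2.sf(statistic, df)),
        design=design,
        low_expected=bool((expected < 5).any()),
    )


def chisq_even(observed: Sequence[int]) -> ChiSquareResult:
    """Goodness of fit against an even distribution over the categories."""
    obs = np.asarray(observed, dtype=float)
    total = obs.sum()
    if total <= 0:
        raise UsageError("chisq_even requires a positive total count")
    expected = np.full_like(obs, total / len(obs))
    return _pearson(obs, expected, "even")


def chisq_subset_vs_background(
    subset: Sequence[int], background: Sequence[int]
) -> ChiSquareResult:
    """Subset branch distribution against background-proportional expectation."""
    sub = np.asarray(subset, dtype=float)
    bg = np.asarray(background, dtype=float)
    if len(sub) != len(bg):
        raise UsageError("subset and background must have equal length")
    if (bg <= 0).any():
        zero = [i for i, v in enumerate(bg) if v <= 0]
        raise UsageError(
            f"background cells {zero} are zero; merge categories before testing"
        )
    expected = sub.sum() * bg / bg.sum()
    return _pearson(sub, expected, "subset_vs_background")


@dataclass(frozen=True)
class PairwiseResult:
    branch_a: str
    branch_b: str
    testable: bool
    result: ChiSquareResult | None


def chisq_pairwise(
    counts: Mapping[str, int],
    durations: Mapping[str, float],
    mode: str = "count",
) -> list[PairwiseResult]:
    """All-pairs stem comparisons; raw p-values, no multiplicity correction.

    ``count`` mode asks whether two stems saw equal numbers of gains;
    ``rate`` mode whether gains are proportional to stem durations (equal
    rates).  Pairs with no gains at all are marked untestable.
    """
    if mode not in {"count", "rate"}:
        raise UsageError(f"unknown pairwise mode: {mode!r}")
    names = [n for n in BRANCH_NAMES if n in counts] or sorted(counts)
    if len(names) < 2:
        raise UsageError("pairwise comparison needs at least two branches")
    out: list[PairwiseResult] = []
    for a, b in combinations(names, 2):
        n = counts[a] + counts[b]
        if n == 0:
            out.append(PairwiseResult(a, b, False, None))
            continue
        obs = np.array([counts[a], counts[b]], dtype=float)
        if mode == "count":
            expected = np.array([n / 2.0, n / 2.0])
        else:
            da, db = durations[a], durations[b]
            expected = n * np.array([da, db]) / (da + db)
        res = _pearson(obs, expected, f"pairwise_{mode}")
        out.append(PairwiseResult(a, b, True, res))
    return out


@dataclass(frozen=True)
class ScalingFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def scaling_fit(points: Sequence[tuple[float, float]]) -> ScalingFit:
    """OLS of subset counts on total counts across stems (linear scaling)."""
    if len(points) < 3:
        raise UsageError("scaling fit needs at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise UsageError("zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # constant y carries no variance to explain: R^2 = 0 by convention
    r2 = 0.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return ScalingFit(float(slope), float(intercept), max(0.0, r2), len(points))
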