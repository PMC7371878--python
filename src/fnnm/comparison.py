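"""Group comparison of neighbor-set frequencies.

Each candidate set W yields a 2x2 table — (contains W, lacks W) x (high
group, low group) — tested with the uncorrected Pearson chi-square statistic

    chi2 = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)],

with p from the chi-square distribution on 1 degree of freedom.  Family-wise
error over the whole candidate family is controlled by Holm-Bonferroni
step-down at the configured alpha (0.01 in the analyses this package
reproduces).  Significant sets more frequent in the high-scoring group are
"good" neighbors, those more frequent in the low-scoring group "bad".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .graph_io import NeighborhoodTable
from .mining import support_count

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyCounts",
    "ComparisonResult",
    "contingency_for_set",
    "chi_square_2x2",
    "holm_bonferroni",
    "compare_sets",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 counts: a/b = high group with/without W, c/d = low group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_high(self) -> int:
        return self.a + self.b

    @property
    def n_low(self) -> int:
        return self.c + self.d

    @property
    def freq_high(self) -> float:
        return self.a / self.n_high if self.n_high else float("nan")

    @property
    def freq_low(self) -> float:
        return self.c / self.n_low if self.n_low else float("nan")


@dataclass(frozen=True)
class ComparisonResult:
    members: tuple[str, ...]
    counts: ContingencyCounts
    chi2: float
    p_raw: float
    significant: bool
    direction: str | None  # "good" | "bad", only when significant

    @property
    def size(self) -> int:
        return len(self.members)


def contingency_for_set(
    members: Sequence[str],
    table_high: NeighborhoodTable,
    table_low: NeighborhoodTable,
) -> ContingencyCounts:
    """Count subjects containing/lacking W in each group's table."""
    if table_high.n_subjects == 0 or table_low.n_subjects == 0:
        raise ValueError("both groups must be non-empty")
    a = support_count(table_high, members)
    c = support_count(table_low, members)
    return ContingencyCounts(
        a=a, b=table_high.n_subjects - a, c=c, d=table_low.n_subjects - c
    )


def chi_square_2x2(
    counts: ContingencyCounts, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction
    by default.

    A zero row margin (W in every subject, or in none) carries no frequency
    contrast: chi2 = 0, p = 1.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    n = a + b + c + d
    if n < 1 or counts.n_high < 1 or counts.n_low < 1:
        raise ValueError("both group sizes must be >= 1")
    margin1, margin2 = a + c, b + d
    if margin1 == 0 or margin2 == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff * diff / (counts.n_high * counts.n_low * margin1 * margin2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def holm_bonferroni(p_values: Sequence[float], alpha: float) -> list[bool]:
    """Holm step-down rejections, returned in the input order.

    Sort p ascending; reject while p_(i) <= alpha / (m - i + 1) (1-based i)
    and stop at the first failure.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):  # rank 0-based
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject.tolist()


def compare_sets(
    candidates: Sequence[tuple[str, ...]],
    table_high: NeighborhoodTable,
    table_low: NeighborhoodTable,
    alpha: float = 0.01,
    yates: bool = False,
) -> list[ComparisonResult]:
    """Test every candidate set, Holm-correcting across the whole family.

    Candidates must be deduplicated; one result per candidate, in input
    order.  Direction is "good" when the significant set is more frequent
    among high scorers, "bad" otherwise.
    """
    if not candidates:
        raise ValueError("candidate family is empty")
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate family contains duplicates")
    counts_list = [
        contingency_for_set(members, table_high, table_low) for members in candidates
    ]
    stats_list = [chi_square_2x2(counts, yates=yates) for counts in counts_list]
    low_expected = sum(
        1 for counts in counts_list if _min_expected(counts) < 5.0
    )
    if low_expected:
        logger.warning(
            "%d candidate table(s) have an expected count below 5", low_expected
        )
    rejections = holm_bonferroni([p for _, p in stats_list], alpha)
    results = []
    for members, counts, (chi2, p), sig in zip(
        candidates, counts_list, stats_list, rejections
    ):
        direction = None
        if sig:
            # equal proportions give chi2 = 0, p = 1: never significant
            assert counts.freq_high != counts.freq_low
            direction = "good" if counts.freq_high > counts.freq_low else "bad"
        results.append(
            ComparisonResult(
                members=tuple(members),
                counts=counts,
                chi2=chi2,
                p_raw=p,
                significant=bool(sig),
                direction=direction,
            )
        )
    return results


def _min_expected(counts: ContingencyCounts) -> float:
    n = counts.n_high + counts.n_low
    if n == 0:
        return 0.0
    return min(
        counts.n_high * (counts.a + counts.c),
        counts.n_high * (counts.b + counts.d),
        counts.n_low * (counts.a + counts.c),
        counts.n_low * (counts.b + counts.d),
    ) / n
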