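"""Phenotype tables and high/low group splits at an integer score cutoff.

The splits mirror median dichotomization of integer test scores: subjects
scoring at or above the cutoff are "high", below it "low" (the median score
itself goes to the high group, matching the 17-24 / 36-40 "high" brackets of
the fluid-intelligence and word-memory tests this package was written
around).  Subjects with a missing score are excluded from that test's
analysis only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PhenotypeTable", "GroupAssignment", "read_phenotype_csv", "split_by_cutoff"]


class DegenerateSplitError(ValueError):
    """A cutoff that leaves one group empty."""


@dataclass
class PhenotypeTable:
    """Integer test scores per subject; one column per test."""

    scores: pd.DataFrame  # index: subject_id (str); columns: test names
    ranges: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate subject_ids in phenotype table")
        if self.ranges:
            for test, (lo, hi) in self.ranges.items():
                if test not in self.scores.columns:
                    continue
                col = self.scores[test].dropna()
                bad = col[(col < lo) | (col > hi)]
                if len(bad):
                    raise ValueError(
                        f"{test}: {len(bad)} score(s) outside declared range [{lo}, {hi}]"
                    )

    @property
    def tests(self) -> list[str]:
        return list(self.scores.columns)


@dataclass(frozen=True)
class GroupAssignment:
    """High/low partition of the scored subjects at an integer cutoff."""

    high: tuple[str, ...]
    low: tuple[str, ...]
    cutoff: int
    rule: str

    @property
    def n_high(self) -> int:
        return len(self.high)

    @property
    def n_low(self) -> int:
        return len(self.low)


def read_phenotype_csv(path, subject_column: str = "Subject") -> PhenotypeTable:
    df = pd.read_csv(path, dtype={subject_column: str})
    if subject_column not in df.columns:
        raise ValueError(f"phenotype CSV has no {subject_column!r} column")
    df = df.set_index(subject_column)
    return PhenotypeTable(scores=df)


def _resolve_median_cutoff(scores: pd.Series) -> int:
    """Sample median, rounded up to an attained integer score."""
    med = float(scores.median())
    cut = math.ceil(med)
    attained = sorted(int(s) for s in scores.unique())
    for s in attained:
        if s >= cut:
            return s
    return attained[-1]


def split_by_cutoff(
    table: PhenotypeTable, test: str, cutoff: int | str
) -> GroupAssignment:
    """Partition subjects: score >= cutoff -> high, score < cutoff -> low.

    ``cutoff="median"`` resolves to the sample median rounded up to an
    attained integer score.  Missing scores drop the subject from this
    test's split (logged); either group ending up empty is an error.
    """
    if test not in table.scores.columns:
        raise KeyError(f"unknown test {test!r}")
    col = table.scores[test]
    missing = col[col.isna()].index.tolist()
    if missing:
        logger.info("%s: %d subject(s) with missing scores excluded", test, len(missing))
    scored = col.dropna()
    if len(scored) < 2:
        raise ValueError(f"{test}: need >= 2 scored subjects, have {len(scored)}")
    if cutoff == "median":
        cut = _resolve_median_cutoff(scored)
        rule = f"{test} >= {cut} (median rule)"
    else:
        cut = int(cutoff)
        rule = f"{test} >= {cut}"
    high = tuple(scored[scored >= cut].index)
    low = tuple(scored[scored < cut].index)
    if not high or not low:
        raise DegenerateSplitError(
            f"{test}: cutoff {cut} leaves an empty group "
            f"(high={len(high)}, low={len(low)})"
        )
    return GroupAssignment(high=high, low=low, cutoff=cut, rule=rule)
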