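"""Apriori-style mining of k-frequent neighbor sets.

A candidate set W is k-frequent when W is a subset of at least k subjects'
neighbor sets; with a fractional threshold t over N subjects the support
bound is k = ceil(t * N), the smallest integer with k/N >= t.  Mining is
levelwise: size-(m+1) candidates are prefix-joins of frequent size-m sets,
pruned by downward closure (every subset of a frequent set is frequent), and
supports are exact row counts on the binary membership matrix.

:func:`brute_force_frequent_sets` is an independent exhaustive enumerator
kept deliberately naive; it exists to cross-check the apriori path on small
tables and refuses large universes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .graph_io import NeighborhoodTable

__all__ = [
    "MiningConfig",
    "FrequentSetRecord",
    "support_count",
    "mine_frequent_sets",
    "brute_force_frequent_sets",
]


@dataclass(frozen=True)
class MiningConfig:
    """Frequency threshold and size cap for one mining run.

    ``threshold_fraction`` in (0, 1] is the minimum support as a fraction of
    the table's subjects; ``max_size`` caps the mined set size (4 in the
    hippocampus analyses this package was built for).
    """

    threshold_fraction: float
    max_size: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")

    def min_support_count(self, n_subjects: int) -> int:
        """Smallest integer k with k/N >= threshold_fraction."""
        if n_subjects < 1:
            raise ValueError("need at least one subject")
        k = math.ceil(self.threshold_fraction * n_subjects - 1e-12)
        return max(k, 1)


@dataclass(frozen=True)
class FrequentSetRecord:
    """A mined neighbor set with its exact support."""

    members: tuple[str, ...]
    support_count: int
    support_fraction: float

    @property
    def size(self) -> int:
        return len(self.members)


def support_count(table: NeighborhoodTable, members: Iterable[str]) -> int:
    """Number of subjects whose neighbor set contains every member.

    The empty set is a subset of every neighbor set, so its support is N.
    """
    cols = table.columns_for(members)
    if not cols:
        return table.n_subjects
    return int(table.membership[:, cols].all(axis=1).sum())


def _records(
    sets_with_masks: Iterable[tuple[tuple[str, ...], np.ndarray]], n: int
) -> list[FrequentSetRecord]:
    out = []
    for members, mask in sets_with_masks:
        c = int(mask.sum())
        out.append(FrequentSetRecord(members, c, c / n))
    return out


def mine_frequent_sets(
    table: NeighborhoodTable, config: MiningConfig
) -> list[FrequentSetRecord]:
    """All sets W with 1 <= |W| <= max_size and support >= ceil(t*N).

    Output is sorted by (size, lexicographic members).  Each level keeps the
    boolean row mask of its sets so level-(m+1) supports are single ANDs.
    """
    n = table.n_subjects
    if n < 1:
        raise ValueError("table has no subjects")
    if not table.candidate_nodes:
        raise ValueError("candidate universe is empty")
    min_count = config.min_support_count(n)

    m = table.membership
    # level 1: frequent singletons
    level: dict[tuple[str, ...], np.ndarray] = {}
    for j, v in enumerate(table.candidate_nodes):
        mask = m[:, j]
        if int(mask.sum()) >= min_count:
            level[(v,)] = mask
    results: list[FrequentSetRecord] = _records(sorted(level.items()), n)

    size = 1
    while level and size < config.max_size:
        keys = sorted(level)
        frequent_at_level = set(keys)
        nxt: dict[tuple[str, ...], np.ndarray] = {}
        # prefix join: two sorted size-m sets sharing their first m-1 members
        for i, a in enumerate(keys):
            prefix = a[:-1]
            for b in keys[i + 1 :]:
                if b[:-1] != prefix:
                    break
                cand = a + (b[-1],)
                # downward-closure prune: every m-subset must be frequent
                if size >= 2 and any(
                    sub not in frequent_at_level
                    for sub in combinations(cand, size)
                ):
                    continue
                mask = level[a] & level[b]
                if int(mask.sum()) >= min_count:
                    nxt[cand] = mask
        results.extend(_records(sorted(nxt.items()), n))
        level = nxt
        size += 1
    return results


def brute_force_frequent_sets(
    table: NeighborhoodTable,
    config: MiningConfig,
    active_column_guard: int = 25,
) -> list[FrequentSetRecord]:
    """Exhaustive enumeration oracle; same contract as mine_frequent_sets.

    Only nodes appearing in at least one subject's neighbor set can belong
    to a frequent set, so enumeration runs over those "active" columns; the
    guard refuses universes whose active-column count would blow up.
    """
    n = table.n_subjects
    if n < 1:
        raise ValueError("table has no subjects")
    min_count = config.min_support_count(n)
    active = [
        v
        for j, v in enumerate(table.candidate_nodes)
        if table.membership[:, j].any()
    ]
    if len(active) > active_column_guard:
        raise ValueError(
            f"{len(active)} active columns exceed the brute-force guard "
            f"({active_column_guard})"
        )
    out: list[FrequentSetRecord] = []
    for size in range(1, config.max_size + 1):
        for members in combinations(sorted(active), size):
            c = support_count(table, members)
            if c >= min_count:
                out.append(FrequentSetRecord(members, c, c / n))
    return out


def records_to_rows(
    records: Sequence[FrequentSetRecord], group: str = ""
) -> list[dict]:
    """Flatten records for TSV output (members semicolon-joined)."""
    return [
        {
            "members": ";".join(r.members),
            "size": r.size,
            "support_count": r.support_count,
            "support_fraction": r.support_fraction,
            "group": group,
        }
        for r in records
    ]
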