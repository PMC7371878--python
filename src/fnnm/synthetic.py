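"""Synthetic graph cohorts with planted neighbor-set structure.

The generator emulates the statistical skeleton of a structural-connectome
cohort study: N subjects share a 463-label vertex universe, each subject's
graph carries edges from one or two target nodes to a random neighbor set,
and integer test scores place each subject deterministically on one side of
a cutoff.  Candidate neighbors enter a subject's neighbor set through
independent per-candidate baseline draws, while *planted* sets are inserted
atomically — all members at once, with a group-specific probability — so a
planted set's ground-truth support is an exact Bernoulli count and recovery
by the mining + comparison pipeline is analyzable.  Background edges among
non-target nodes pad the files to realistic graph sizes without affecting
any neighbor set.

Everything is reproducible from one integer seed: a root SeedSequence
drives membership, score, and per-subject background-edge substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .graph_io import CohortManifest, NeighborhoodTable, read_manifest
from .phenotype import PhenotypeTable

__all__ = [
    "PlantedSet",
    "SyntheticCohortSpec",
    "default_node_universe",
    "simulate_membership",
    "generate_cohort",
    "null_cohort",
]

_SUBCORTICAL = [
    "Left-Hippocampus",
    "Right-Hippocampus",
    "Left-Caudate",
    "Right-Caudate",
    "Left-Putamen",
    "Right-Putamen",
    "Left-Pallidum",
    "Right-Pallidum",
    "Left-Thalamus",
    "Right-Thalamus",
    "Left-Amygdala",
    "Right-Amygdala",
    "Left-Accumbens-area",
    "Right-Accumbens-area",
    "Brain-Stem",
]

_CORTICAL_REGIONS = [
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
]


def default_node_universe(n_nodes: int = 463) -> tuple[str, ...]:
    """Parcellation-style label universe (cortical subdivisions per
    hemisphere plus subcortical structures), exactly ``n_nodes`` labels."""
    labels = list(_SUBCORTICAL)
    i = 1
    while len(labels) < n_nodes:
        for hemi in ("lh", "rh"):
            for region in _CORTICAL_REGIONS:
                labels.append(f"{hemi}.{region}_{i}")
                if len(labels) == n_nodes:
                    return tuple(labels)
        i += 1
    return tuple(labels[:n_nodes])


@dataclass(frozen=True)
class PlantedSet:
    """A neighbor set inserted atomically with group-specific probability.

    ``attach_to`` indexes the target node whose adjacency carries the
    planted edges (relevant only for two-target specs).
    """

    members: tuple[str, ...]
    p_high: float
    p_low: float
    attach_to: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_high <= 1.0 and 0.0 <= self.p_low <= 1.0):
            raise ValueError("planted probabilities must lie in [0, 1]")
        if not self.members:
            raise ValueError("planted set has no members")

    @property
    def differential(self) -> bool:
        return self.p_high != self.p_low


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for one synthetic cohort.

    Defaults mirror the cohort scale the method targets: 413 subjects split
    near the score median, a 463-label universe, and baseline inclusion
    probabilities spread over (0.05, 0.6) so that only planted structure
    clears high frequency thresholds.
    """

    seed: int
    n_high: int = 207
    n_low: int = 206
    node_universe: tuple[str, ...] = field(default_factory=default_node_universe)
    target_nodes: tuple[str, ...] = ("Left-Hippocampus",)
    planted_sets: tuple[PlantedSet, ...] = ()
    baseline_prob_range: tuple[float, float] = (0.05, 0.6)
    background_edge_prob: float = 0.02
    baseline_on_planted_members: bool = False
    test_name: str = "PMAT24_A_CR"
    score_range: tuple[int, int] = (0, 24)
    cutoff: int = 17

    def __post_init__(self) -> None:
        if self.n_high < 1 or self.n_low < 1 or self.n_high + self.n_low < 2:
            raise ValueError("need at least one subject per group")
        lo, hi = self.baseline_prob_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("baseline_prob_range must be ordered within [0, 1]")
        if not (0.0 <= self.background_edge_prob <= 1.0):
            raise ValueError("background_edge_prob must lie in [0, 1]")
        if not (1 <= len(self.target_nodes) <= 2):
            raise ValueError("one or two target nodes supported")
        universe = set(self.node_universe)
        for t in self.target_nodes:
            if t not in universe:
                raise ValueError(f"target {t!r} not in node universe")
        seen: set[str] = set(self.target_nodes)
        for ps in self.planted_sets:
            members = set(ps.members)
            if not members <= universe:
                raise ValueError(f"planted members {members} outside universe")
            if members & seen:
                raise ValueError("planted sets must be disjoint from each other and targets")
            seen |= members
            if not (0 <= ps.attach_to < len(self.target_nodes)):
                raise ValueError("attach_to out of range")
        smin, smax = self.score_range
        if not (smin < self.cutoff <= smax):
            raise ValueError("cutoff must satisfy score_min < cutoff <= score_max")


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort."""

    planted: list[PlantedSet]
    n_high: int
    n_low: int
    seed: int
    subject_groups: dict[str, str]

    @property
    def differential_sets(self) -> list[PlantedSet]:
        return [p for p in self.planted if p.differential]

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "planted_sets": [
                {
                    "members": list(p.members),
                    "p_high": p.p_high,
                    "p_low": p.p_low,
                    "differential": p.differential,
                }
                for p in self.planted
            ],
            "n_differential_sets": len(self.differential_sets),
            "subject_groups": self.subject_groups,
        }


def _subject_ids(spec: SyntheticCohortSpec) -> tuple[list[str], list[str]]:
    width = len(str(spec.n_high + spec.n_low))
    all_ids = [f"sub-{i:0{width}d}" for i in range(1, spec.n_high + spec.n_low + 1)]
    return all_ids[: spec.n_high], all_ids[spec.n_high :]


def simulate_membership(
    spec: SyntheticCohortSpec,
) -> tuple[NeighborhoodTable, NeighborhoodTable, list[np.ndarray], CohortTruth]:
    """Draw the per-subject neighbor-set membership matrices in memory.

    Returns the high-group and low-group union-neighborhood tables (these
    are what mining consumes), the per-target membership stack (ordered
    high rows then low rows, one matrix per target node) used when graph
    files are written, and the cohort truth record.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    high_ids, low_ids = _subject_ids(spec)
    candidates = sorted(set(spec.node_universe) - set(spec.target_nodes))
    col = {v: j for j, v in enumerate(candidates)}
    n_total = spec.n_high + spec.n_low
    lo, hi = spec.baseline_prob_range
    baseline = rng.uniform(lo, hi, size=len(candidates))
    if not spec.baseline_on_planted_members:
        # planted members enter only through the atomic draw, so a planted
        # set's support is exactly its Bernoulli count (the default; the
        # mixed mode layers baseline inclusion on top for harder recovery)
        for ps in spec.planted_sets:
            for m in ps.members:
                baseline[col[m]] = 0.0

    per_target = [
        rng.random((n_total, len(candidates))) < baseline[None, :]
        for _ in spec.target_nodes
    ]
    for ps in spec.planted_sets:
        p_vec = np.concatenate(
            [np.full(spec.n_high, ps.p_high), np.full(spec.n_low, ps.p_low)]
        )
        drawn = rng.random(n_total) < p_vec
        cols = [col[m] for m in ps.members]
        # atomic insertion: all members appear together in the drawn subjects
        per_target[ps.attach_to][np.ix_(drawn.nonzero()[0], cols)] = True

    union = per_target[0]
    for m in per_target[1:]:
        union = union | m
    table_high = NeighborhoodTable(high_ids, candidates, union[: spec.n_high])
    table_low = NeighborhoodTable(low_ids, candidates, union[spec.n_high :])
    truth = CohortTruth(
        planted=list(spec.planted_sets),
        n_high=spec.n_high,
        n_low=spec.n_low,
        seed=spec.seed,
        subject_groups={**{s: "high" for s in high_ids}, **{s: "low" for s in low_ids}},
    )
    return table_high, table_low, per_target, truth


def _draw_scores(spec: SyntheticCohortSpec, rng: np.random.Generator) -> pd.Series:
    high_ids, low_ids = _subject_ids(spec)
    smin, smax = spec.score_range
    high_scores = rng.integers(spec.cutoff, smax + 1, size=len(high_ids))
    low_scores = rng.integers(smin, spec.cutoff, size=len(low_ids))
    return pd.Series(
        np.concatenate([high_scores, low_scores]),
        index=high_ids + low_ids,
        name=spec.test_name,
    )


def generate_cohort(
    spec: SyntheticCohortSpec, outdir: str | Path
) -> tuple[CohortManifest, PhenotypeTable, CohortTruth]:
    """Write a full on-disk cohort: graph files, manifest, nodes file,
    phenotype CSV, and truth JSON.

    Per subject, edges {target, v} are emitted for every v in the target's
    simulated neighbor set, plus Bernoulli background edges among
    non-target node pairs (drawn from a per-subject substream).  Output is
    byte-deterministic for a fixed spec.
    """
    outdir = Path(outdir)
    (outdir / "graphs").mkdir(parents=True, exist_ok=True)
    table_high, table_low, per_target, truth = simulate_membership(spec)
    rng_scores = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    scores = _draw_scores(spec, rng_scores)

    candidates = table_high.candidate_nodes
    high_ids, low_ids = _subject_ids(spec)
    all_ids = high_ids + low_ids
    non_target = [v for v in spec.node_universe if v not in spec.target_nodes]
    bg_pairs = [
        (a, b)
        for i, a in enumerate(non_target)
        for b in non_target[i + 1 :]
    ]
    bg_pairs = [tuple(sorted(p)) for p in bg_pairs]

    manifest_rows = []
    for i, sid in enumerate(all_ids):
        edges: set[tuple[str, str]] = set()
        for t_idx, target in enumerate(spec.target_nodes):
            row = per_target[t_idx][i]
            for j in row.nonzero()[0]:
                edges.add(tuple(sorted((target, candidates[j]))))
        if len(spec.target_nodes) == 2:
            edges.add(tuple(sorted(spec.target_nodes)))
        if spec.background_edge_prob > 0 and bg_pairs:
            sub_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 2, i])
            )
            mask = sub_rng.random(len(bg_pairs)) < spec.background_edge_prob
            for k in mask.nonzero()[0]:
                edges.add(bg_pairs[k])
        gpath = outdir / "graphs" / f"{sid}.csv"
        with open(gpath, "w") as fh:
            for a, b in sorted(edges):
                fh.write(f"{a},{b}\n")
        manifest_rows.append((sid, f"graphs/{sid}.csv"))

    with open(outdir / "manifest.csv", "w") as fh:
        fh.write("subject_id,path\n")
        for sid, rel in manifest_rows:
            fh.write(f"{sid},{rel}\n")
    with open(outdir / "nodes.txt", "w") as fh:
        for v in spec.node_universe:
            fh.write(v + "\n")
    pheno = pd.DataFrame({spec.test_name: scores})
    pheno.index.name = "Subject"
    pheno.to_csv(outdir / "phenotype.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = read_manifest(outdir / "manifest.csv", outdir / "nodes.txt")
    return manifest, PhenotypeTable(scores=pheno), truth


def null_cohort(
    spec: SyntheticCohortSpec, outdir: str | Path
) -> tuple[CohortManifest, PhenotypeTable, CohortTruth]:
    """generate_cohort with the no-group-difference constraint enforced."""
    _check_null(spec)
    return generate_cohort(spec, outdir)


def null_membership(
    spec: SyntheticCohortSpec,
) -> tuple[NeighborhoodTable, NeighborhoodTable, CohortTruth]:
    """In-memory membership draw for a null cohort (FWER calibration)."""
    _check_null(spec)
    table_high, table_low, _, truth = simulate_membership(spec)
    return table_high, table_low, truth


def _check_null(spec: SyntheticCohortSpec) -> None:
    for ps in spec.planted_sets:
        if ps.differential:
            raise ValueError(
                f"null cohort requires p_high == p_low; planted set "
                f"{ps.members} has ({ps.p_high}, {ps.p_low})"
            )


def with_swapped_probabilities(spec: SyntheticCohortSpec) -> SyntheticCohortSpec:
    """Same cohort spec with every planted set's group probabilities swapped."""
    return replace(
        spec,
        planted_sets=tuple(
            replace(ps, p_high=ps.p_low, p_low=ps.p_high) for ps in spec.planted_sets
        ),
    )
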