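"""Orchestration: mine per group, compare, and write report tables.

One *analysis* is a (target spec, frequency threshold, test, cutoff, alpha,
max size) tuple.  For each analysis the cohort is split into high/low score
groups, frequent neighbor sets are mined within each group at that group's
own N, the union of the two groups' frequent sets forms the candidate
family, and every candidate is chi-square tested with Holm step-down
correction across the family.  The summary output mirrors the familiar
per-target report shape: frequent-set counts by size for each group, the
significant-set count, and its good/bad split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .comparison import ComparisonResult, compare_sets
from .graph_io import (
    CohortManifest,
    NeighborhoodTable,
    TargetSpec,
    build_table_from_graphs,
    load_cohort_graphs,
    read_manifest,
)
from .mining import FrequentSetRecord, MiningConfig, mine_frequent_sets
from .phenotype import GroupAssignment, PhenotypeTable, read_phenotype_csv, split_by_cutoff

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisSpec",
    "RunConfig",
    "AnalysisOutput",
    "SummaryRow",
    "analyze_tables",
    "run_analysis",
    "write_reports",
    "load_run_config",
]


@dataclass(frozen=True)
class AnalysisSpec:
    """One (target, test) analysis configuration."""

    name: str
    target_nodes: tuple[str, ...]
    test: str
    cutoff: int | str = "median"
    threshold_fraction: float = 0.8
    max_size: int = 4
    alpha: float = 0.01
    cohort_wide_threshold: bool = False
    yates: bool = False


@dataclass
class RunConfig:
    manifest_path: Path
    phenotype_path: Path
    analyses: list[AnalysisSpec]
    nodes_path: Path | None = None
    output_dir: Path = Path("fnnm_out")

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ValueError("run config lists no analyses")


@dataclass
class SummaryRow:
    """One group's line of the per-target summary table."""

    target: str
    test: str
    group: str
    n_subjects: int
    size_counts: list[int]
    significant: int
    significant_for_group: int


@dataclass
class AnalysisOutput:
    spec: AnalysisSpec
    assignment: GroupAssignment
    frequent_high: list[FrequentSetRecord]
    frequent_low: list[FrequentSetRecord]
    results: list[ComparisonResult]
    summary: list[SummaryRow]

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.results)

    @property
    def n_good(self) -> int:
        return sum(r.significant and r.direction == "good" for r in self.results)

    @property
    def n_bad(self) -> int:
        return sum(r.significant and r.direction == "bad" for r in self.results)


def _size_counts(records: Sequence[FrequentSetRecord], max_size: int) -> list[int]:
    counts = [0] * max_size
    for r in records:
        counts[r.size - 1] += 1
    return counts


def analyze_tables(
    table_high: NeighborhoodTable,
    table_low: NeighborhoodTable,
    spec: AnalysisSpec,
    assignment: GroupAssignment | None = None,
) -> AnalysisOutput:
    """Mine each group's table, pool candidates, test, and summarize.

    With ``cohort_wide_threshold`` the minimum support count is derived
    from the pooled N and applied to both groups; the default derives it
    per group from that group's own N.
    """
    config = MiningConfig(spec.threshold_fraction, spec.max_size)
    if spec.cohort_wide_threshold:
        pooled_n = table_high.n_subjects + table_low.n_subjects
        k = config.min_support_count(pooled_n)
        # same absolute count bound inside each group, expressed as a fraction
        freq_high = mine_frequent_sets(
            table_high, MiningConfig(min(k / table_high.n_subjects, 1.0), spec.max_size)
        )
        freq_low = mine_frequent_sets(
            table_low, MiningConfig(min(k / table_low.n_subjects, 1.0), spec.max_size)
        )
    else:
        freq_high = mine_frequent_sets(table_high, config)
        freq_low = mine_frequent_sets(table_low, config)

    candidates = sorted(
        {r.members for r in freq_high} | {r.members for r in freq_low},
        key=lambda m: (len(m), m),
    )
    if candidates:
        results = compare_sets(
            candidates, table_high, table_low, alpha=spec.alpha, yates=spec.yates
        )
    else:
        logger.info("%s: candidate family is empty; nothing to test", spec.name)
        results = []

    n_sig = sum(r.significant for r in results)
    n_good = sum(r.significant and r.direction == "good" for r in results)
    n_bad = n_sig - n_good
    if assignment is None:
        assignment = GroupAssignment(
            high=tuple(table_high.subject_ids),
            low=tuple(table_low.subject_ids),
            cutoff=0,
            rule="pre-assigned groups",
        )
    summary = [
        SummaryRow(
            target=spec.name,
            test=spec.test,
            group="high",
            n_subjects=table_high.n_subjects,
            size_counts=_size_counts(freq_high, spec.max_size),
            significant=n_sig,
            significant_for_group=n_good,
        ),
        SummaryRow(
            target=spec.name,
            test=spec.test,
            group="low",
            n_subjects=table_low.n_subjects,
            size_counts=_size_counts(freq_low, spec.max_size),
            significant=n_sig,
            significant_for_group=n_bad,
        ),
    ]
    return AnalysisOutput(
        spec=spec,
        assignment=assignment,
        frequent_high=freq_high,
        frequent_low=freq_low,
        results=results,
        summary=summary,
    )


def run_analysis(
    config: RunConfig,
    manifest: CohortManifest | None = None,
    phenotype: PhenotypeTable | None = None,
) -> tuple[list[AnalysisOutput], list[str]]:
    """Run every configured analysis over one shared cohort load.

    A failing analysis (degenerate split, empty family, bad target) is
    recorded in the returned error list without aborting its siblings.
    """
    if manifest is None:
        manifest = read_manifest(config.manifest_path, config.nodes_path)
    if phenotype is None:
        phenotype = read_phenotype_csv(config.phenotype_path)
    common = [sid for sid in manifest.subject_ids if sid in phenotype.scores.index]
    if not common:
        raise ValueError("manifest and phenotype share no subjects")
    logger.info(
        "cohort: %d manifest subjects, %d with phenotype records",
        len(manifest), len(common),
    )
    graphs_all = load_cohort_graphs(manifest)
    graphs = [g for g in graphs_all if g.subject_id in set(common)]

    outputs: list[AnalysisOutput] = []
    errors: list[str] = []
    for spec in config.analyses:
        try:
            assignment = split_by_cutoff(phenotype, spec.test, spec.cutoff)
            target_spec = TargetSpec(target_nodes=spec.target_nodes)
            table = build_table_from_graphs(
                graphs, manifest.node_universe, target_spec
            )
            high_ids = [s for s in assignment.high if s in set(table.subject_ids)]
            low_ids = [s for s in assignment.low if s in set(table.subject_ids)]
            if not high_ids or not low_ids:
                raise ValueError(f"{spec.name}: a group has no graphed subjects")
            logger.info(
                "%s: realized N=%d (high=%d, low=%d), rule: %s",
                spec.name, len(high_ids) + len(low_ids),
                len(high_ids), len(low_ids), assignment.rule,
            )
            out = analyze_tables(
                table.restrict_rows(high_ids),
                table.restrict_rows(low_ids),
                spec,
                assignment=assignment,
            )
            logger.info(
                "%s: %d frequent (high), %d frequent (low), family=%d, "
                "significant=%d (good=%d, bad=%d)",
                spec.name, len(out.frequent_high), len(out.frequent_low),
                len(out.results), out.n_significant, out.n_good, out.n_bad,
            )
            outputs.append(out)
        except Exception as exc:
            logger.error("analysis %s failed: %s", spec.name, exc)
            errors.append(f"{spec.name}: {exc}")
    return outputs, errors


_SUMMARY_HEADER = [
    "target", "test", "group", "n_subjects",
    "size_1", "size_2", "size_3", "size_4",
    "significant", "significant_for_group",
]


def write_reports(
    outputs: Sequence[AnalysisOutput],
    outdir: str | Path,
    metadata: dict | None = None,
) -> list[Path]:
    """Write the summary TSV, per-analysis listings, and run metadata.

    Listings are sorted by (size, members) and one file per direction is
    written even when empty (header-only), so a run's output inventory is
    fixed by its configuration.
    """
    if not outputs:
        raise ValueError("no analysis outputs to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary_path = outdir / "summary.tsv"
    with open(summary_path, "w") as fh:
        fh.write("\t".join(_SUMMARY_HEADER) + "\n")
        for out in outputs:
            for row in out.summary:
                sizes = (row.size_counts + [0] * 4)[:4]
                fh.write(
                    "\t".join(
                        str(x)
                        for x in [
                            row.target, row.test, row.group, row.n_subjects,
                            *sizes, row.significant, row.significant_for_group,
                        ]
                    )
                    + "\n"
                )
    written.append(summary_path)

    listing_header = [
        "members", "size", "count_high", "n_high", "count_low", "n_low",
        "freq_high", "freq_low", "chi2", "p_raw", "significant", "direction",
    ]
    for out in outputs:
        ordered = sorted(out.results, key=lambda r: (r.size, r.members))
        files = {
            "all": ordered,
            "good": [r for r in ordered if r.significant and r.direction == "good"],
            "bad": [r for r in ordered if r.significant and r.direction == "bad"],
        }
        for tag, rows in files.items():
            path = outdir / f"{out.spec.name}_{out.spec.test}_{tag}.tsv"
            with open(path, "w") as fh:
                fh.write("\t".join(listing_header) + "\n")
                for r in rows:
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in [
                                ";".join(r.members), r.size,
                                r.counts.a, r.counts.n_high,
                                r.counts.c, r.counts.n_low,
                                f"{r.counts.freq_high:.6f}",
                                f"{r.counts.freq_low:.6f}",
                                f"{r.chi2:.6f}", f"{r.p_raw:.6g}",
                                int(r.significant), r.direction or "",
                            ]
                        )
                        + "\n"
                    )
            written.append(path)

    meta = {
        "fnnm_version": __version__,
        "analyses": [
            {
                "name": out.spec.name,
                "test": out.spec.test,
                "targets": list(out.spec.target_nodes),
                "threshold_fraction": out.spec.threshold_fraction,
                "max_size": out.spec.max_size,
                "alpha": out.spec.alpha,
                "cutoff": out.assignment.cutoff,
                "rule": out.assignment.rule,
                "n_high": len(out.assignment.high),
                "n_low": len(out.assignment.low),
                "n_candidates": len(out.results),
                "n_significant": out.n_significant,
                "n_good": out.n_good,
                "n_bad": out.n_bad,
            }
            for out in outputs
        ],
    }
    if metadata:
        meta.update(metadata)
    meta_path = outdir / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(meta_path)
    return written


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration.

    Schema::

        manifest: manifest.csv
        nodes: nodes.txt          # optional
        phenotype: phenotype.csv
        output: out/              # optional
        analyses:
          - name: left_pmat
            targets: [Left-Hippocampus]
            test: PMAT24_A_CR
            cutoff: 17            # or "median"
            threshold: 0.8
            max_size: 4
            alpha: 0.01
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    analyses = []
    for entry in raw.get("analyses", []):
        analyses.append(
            AnalysisSpec(
                name=entry["name"],
                target_nodes=tuple(entry["targets"]),
                test=entry["test"],
                cutoff=entry.get("cutoff", "median"),
                threshold_fraction=float(entry.get("threshold", 0.8)),
                max_size=int(entry.get("max_size", 4)),
                alpha=float(entry.get("alpha", 0.01)),
                cohort_wide_threshold=bool(entry.get("cohort_wide_threshold", False)),
                yates=bool(entry.get("yates", False)),
            )
        )
    return RunConfig(
        manifest_path=_resolve(raw["manifest"]),
        phenotype_path=_resolve(raw["phenotype"]),
        nodes_path=_resolve(raw["nodes"]) if raw.get("nodes") else None,
        output_dir=_resolve(raw.get("output", "fnnm_out")),
        analyses=analyses,
    )
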