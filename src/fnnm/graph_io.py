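"""Reading graph cohorts and materializing per-subject neighbor sets.

A cohort is a collection of undirected, unweighted graphs that share one
labelled vertex set (one graph per subject, e.g. structural connectomes on a
common parcellation).  The quantity everything downstream consumes is the
neighbor set Gamma_i(u) of a designated target node u in subject i's graph —
or, for a multi-target specification, the union of the targets' neighbor
sets.  :func:`build_neighborhood_table` materializes all of these as one
binary subjects x candidate-nodes membership matrix.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectGraph",
    "CohortManifest",
    "TargetSpec",
    "NeighborhoodTable",
    "read_subject_graph",
    "write_subject_graph",
    "read_manifest",
    "neighbor_set",
    "load_cohort_graphs",
    "build_table_from_graphs",
    "build_neighborhood_table",
]


class GraphParseError(ValueError):
    """A graph file exists but does not parse in the declared format."""


class MissingNodeError(KeyError):
    """A target node is absent from a subject's vertex set."""


@dataclass(frozen=True)
class SubjectGraph:
    """One subject's undirected labelled graph.

    Edges are stored as frozensets of two labels, so ``{a, b}`` and
    ``{b, a}`` collapse to one edge and self-loops cannot be represented.
    """

    subject_id: str
    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"edge {set(e)} is not an unordered pair")
            if not e <= self.nodes:
                raise ValueError(f"edge {set(e)} references unknown nodes")

    def neighbors(self, node: str) -> set[str]:
        return {next(iter(e - {node})) for e in self.edges if node in e}


@dataclass
class CohortManifest:
    """Ordered subject -> graph-file mapping plus the shared vertex universe."""

    entries: list[tuple[str, Path]]
    node_universe: frozenset[str]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("manifest contains duplicate subject_ids")
        if not self.node_universe:
            raise ValueError("node universe is empty")

    @property
    def subject_ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TargetSpec:
    """Which node(s) to take the neighborhood of, and which labels to drop
    from the candidate-neighbor universe.

    The targets themselves are always excluded: a node is never its own
    candidate neighbor.  Two targets give the union variant (the neighbor
    set is the union of the two adjacency lists).
    """

    target_nodes: tuple[str, ...]
    excluded_nodes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.target_nodes:
            raise ValueError("target_nodes must be non-empty")
        if len(set(self.target_nodes)) != len(self.target_nodes):
            raise ValueError("target_nodes contains duplicates")
        # targets are never candidate neighbors of themselves
        object.__setattr__(
            self, "excluded_nodes", self.excluded_nodes | set(self.target_nodes)
        )


@dataclass
class NeighborhoodTable:
    """Binary subjects x candidate-nodes membership matrix.

    ``membership[i, j]`` is True iff candidate node ``candidate_nodes[j]``
    lies in subject ``subject_ids[i]``'s neighbor set of the target spec.
    """

    subject_ids: list[str]
    candidate_nodes: list[str]
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != (len(self.subject_ids), len(self.candidate_nodes)):
            raise ValueError(
                f"membership shape {self.membership.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.candidate_nodes)} candidates"
            )
        self._col_index = {v: j for j, v in enumerate(self.candidate_nodes)}

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def columns_for(self, members: Iterable[str]) -> list[int]:
        try:
            return [self._col_index[v] for v in members]
        except KeyError as exc:
            raise KeyError(f"node {exc.args[0]!r} is not a candidate node") from None

    def restrict_rows(self, subject_ids: Sequence[str]) -> "NeighborhoodTable":
        """Row-subset in the given subject order (e.g. one phenotype group)."""
        index = {sid: i for i, sid in enumerate(self.subject_ids)}
        rows = [index[sid] for sid in subject_ids]
        return NeighborhoodTable(
            subject_ids=list(subject_ids),
            candidate_nodes=self.candidate_nodes,
            membership=self.membership[rows, :],
        )


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _looks_like_header(fields: Sequence[str]) -> bool:
    # a numeric-looking third (weight) column marks a data row; header rows
    # are recognised by common column-name words
    lowered = [f.strip().lower() for f in fields]
    header_words = {"source", "target", "from", "to", "node1", "node2", "weight", "id_a", "id_b"}
    return any(f in header_words for f in lowered)


def _read_edgelist(path: Path, subject_id: str) -> SubjectGraph:
    nodes: set[str] = set()
    edges: set[frozenset[str]] = set()
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            return SubjectGraph(subject_id, frozenset(), frozenset())
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not f.strip() for f in row):
                continue
            if lineno == 1 and _looks_like_header(row):
                continue
            if len(row) < 2:
                raise GraphParseError(
                    f"{path}: line {lineno}: expected two node columns, got {row!r}"
                )
            a, b = row[0].strip(), row[1].strip()
            if not a or not b:
                raise GraphParseError(f"{path}: line {lineno}: empty node label")
            if a == b:
                logger.warning("%s: line %d: self-loop %r dropped", path, lineno, a)
                nodes.add(a)
                continue
            nodes.update((a, b))
            edges.add(frozenset((a, b)))
    return SubjectGraph(subject_id, frozenset(nodes), frozenset(edges))


def _read_graphml(path: Path, subject_id: str) -> SubjectGraph:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # malformed XML etc.
        raise GraphParseError(f"{path}: not parseable as GraphML: {exc}") from exc
    nodes = frozenset(str(n) for n in g.nodes)
    edges: set[frozenset[str]] = set()
    for a, b in g.edges():
        a, b = str(a), str(b)
        if a == b:
            logger.warning("%s: self-loop %r dropped", path, a)
            continue
        edges.add(frozenset((a, b)))
    return SubjectGraph(subject_id, nodes, frozenset(edges))


def read_subject_graph(
    path: str | Path, format: str = "edgelist_csv", subject_id: str | None = None
) -> SubjectGraph:
    """Read one subject's graph from an edge-list CSV/TSV or GraphML file.

    Edges are deduplicated across orientations, self-loops are dropped with
    a warning, and any weight column is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = subject_id if subject_id is not None else path.stem
    if format == "edgelist_csv":
        return _read_edgelist(path, sid)
    if format == "graphml":
        return _read_graphml(path, sid)
    raise ValueError(f"unknown graph format {format!r}")


def write_subject_graph(graph: SubjectGraph, path: str | Path) -> None:
    """Write an edge-list CSV (sorted, one row per undirected edge)."""
    rows = sorted(tuple(sorted(e)) for e in graph.edges)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for a, b in rows:
            writer.writerow([a, b])


def read_manifest(
    manifest_path: str | Path, nodes_path: str | Path | None = None
) -> CohortManifest:
    """Read a cohort manifest CSV (columns subject_id, path).

    Relative graph paths are resolved against the manifest's directory.  The
    node universe comes from ``nodes_path`` (one label per line) when given,
    otherwise from the union of all subjects' vertex sets.
    """
    manifest_path = Path(manifest_path)
    entries: list[tuple[str, Path]] = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"subject_id", "path"} <= set(reader.fieldnames):
            raise GraphParseError(
                f"{manifest_path}: manifest needs 'subject_id' and 'path' columns"
            )
        for row in reader:
            p = Path(row["path"])
            if not p.is_absolute():
                p = manifest_path.parent / p
            entries.append((row["subject_id"].strip(), p))
    if nodes_path is not None:
        with open(nodes_path) as fh:
            universe = frozenset(line.strip() for line in fh if line.strip())
    else:
        universe = frozenset()
        for sid, p in entries:
            universe |= read_subject_graph(p, subject_id=sid).nodes
    return CohortManifest(entries=entries, node_universe=universe)


def neighbor_set(graph: SubjectGraph, spec: TargetSpec) -> set[str]:
    """Union of the targets' neighbor sets, minus the excluded labels.

    Raises :class:`MissingNodeError` if a target node is not in the
    subject's vertex set — a silent empty neighborhood would bias supports
    downward.
    """
    result: set[str] = set()
    for t in spec.target_nodes:
        if t not in graph.nodes:
            raise MissingNodeError(
                f"target node {t!r} absent from subject {graph.subject_id!r}"
            )
        result |= graph.neighbors(t)
    return result - spec.excluded_nodes


def load_cohort_graphs(manifest: CohortManifest) -> list[SubjectGraph]:
    """Read every graph in manifest order (one pass, reusable across specs)."""
    return [read_subject_graph(p, subject_id=sid) for sid, p in manifest.entries]


def build_table_from_graphs(
    graphs: Sequence[SubjectGraph],
    node_universe: frozenset[str] | set[str],
    spec: TargetSpec,
) -> NeighborhoodTable:
    """Materialize Gamma_i(target spec) from already-loaded graphs.

    Candidate nodes are the universe minus the spec's exclusions, in
    lexicographic order; row i is subject i's binary membership vector.
    """
    for t in spec.target_nodes:
        if t not in node_universe:
            raise MissingNodeError(f"target node {t!r} not in the node universe")
    candidates = sorted(set(node_universe) - spec.excluded_nodes)
    if not candidates:
        raise ValueError("candidate universe is empty after exclusions")
    col = {v: j for j, v in enumerate(candidates)}
    membership = np.zeros((len(graphs), len(candidates)), dtype=bool)
    failures: list[str] = []
    for i, graph in enumerate(graphs):
        try:
            gamma = neighbor_set(graph, spec)
        except MissingNodeError:
            failures.append(graph.subject_id)
            continue
        for v in gamma:
            j = col.get(v)
            if j is not None:
                membership[i, j] = True
    if failures:
        raise MissingNodeError(
            f"target node(s) missing in {len(failures)} subject(s): {failures}"
        )
    return NeighborhoodTable(
        subject_ids=[g.subject_id for g in graphs],
        candidate_nodes=candidates,
        membership=membership,
    )


def build_neighborhood_table(
    manifest: CohortManifest, spec: TargetSpec
) -> NeighborhoodTable:
    """Read the manifest's graphs and materialize the membership matrix."""
    return build_table_from_graphs(
        load_cohort_graphs(manifest), manifest.node_universe, spec
    )
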