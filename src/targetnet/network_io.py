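"""Readers, writers and label bookkeeping for protein interaction networks.

The analysis graph is a simple undirected :class:`networkx.Graph` whose nodes
are opaque, case-sensitive protein identifiers.  Interaction sets are ingested
from two-column edge lists; self-loops and duplicate pairs (in either
orientation) are removed on load.  Following the standard preprocessing for
incomplete interactomes, all downstream analyses run on the maximal (largest)
connected component.

Node labels partition the proteome into three classes:

* ``D``   — known drug targets (the positive set),
* ``PT1`` — pending test proteins with a chemical-physical feature vector,
* ``PT2`` — pending test proteins without features.

The target ratio DR = |D| / |P| and pending ratio PR = |PT| / |P| (with
P = D ∪ PT1 ∪ PT2) are the global baselines used by the enrichment
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ProteinNetwork",
    "EdgeListReport",
    "LabeledProteome",
    "FeatureLoadReport",
    "parse_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "assign_labels",
    "read_labels",
    "read_feature_table",
    "coverage_report",
]

#: The in-memory network container.  A plain :class:`networkx.Graph` is used
#: throughout; helpers in this module guarantee it stays simple (no self
#: loops, no parallel edges) and undirected.
ProteinNetwork = nx.Graph


@dataclass(frozen=True)
class EdgeListReport:
    """Accounting of an edge-list load."""

    n_lines: int = 0
    n_comment: int = 0
    n_skipped: int = 0  # lines with fewer than two fields
    n_self_loops: int = 0
    n_duplicates: int = 0


def parse_edge_list(
    path: str | Path, delimiter: str | None = None
) -> tuple[nx.Graph, EdgeListReport]:
    """Read a two-column edge list into a simple undirected graph.

    Parameters
    ----------
    path
        Text file with one interaction per line, ``#`` comments allowed.
    delimiter
        Field separator; ``None`` splits on any whitespace (accepts TSV).

    Returns
    -------
    graph, report
        The graph (self-loops dropped, duplicate pairs collapsed) and a
        load report counting dropped lines.
    """
    g: nx.Graph = nx.Graph()
    n_lines = n_comment = n_skipped = n_self = n_dup = 0
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            n_lines += 1
            if line.startswith("#"):
                n_comment += 1
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                n_skipped += 1
                continue
            u, v = fields[0], fields[1]
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    report = EdgeListReport(n_lines, n_comment, n_skipped, n_self, n_dup)
    return g, report


def write_edge_list(
    net: nx.Graph,
    path: str | Path,
    delimiter: str = "\t",
    header: Iterable[str] = (),
) -> None:
    """Write the network as a two-column edge list (isolated nodes appear as
    self-referential comment lines are *not* emitted; they are lost on a
    round-trip, matching the edge-set round-trip contract)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}{delimiter}{v}\n")


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken by the lexicographically smallest
    member identifier, so the result is deterministic.  An empty network maps
    to an empty network.
    """
    if net.number_of_nodes() == 0:
        return nx.Graph()
    comps = sorted(
        nx.connected_components(net),
        key=lambda c: (-len(c), min(str(x) for x in c)),
    )
    return net.subgraph(comps[0]).copy()


@dataclass
class LabeledProteome:
    """Partition of the analysis nodes into D / PT1 / PT2.

    The three sets are pairwise disjoint and their union is the node set of
    the network the labels were assigned against.
    """

    targets: set = field(default_factory=set)
    pending_featured: set = field(default_factory=set)
    pending_unfeatured: set = field(default_factory=set)
    dropped_targets: int = 0
    dropped_featured: int = 0

    @property
    def pending(self) -> set:
        """All non-target proteins (PT = PT1 ∪ PT2)."""
        return self.pending_featured | self.pending_unfeatured

    @property
    def all_nodes(self) -> set:
        return self.targets | self.pending_featured | self.pending_unfeatured

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_pending(self) -> int:
        return len(self.pending_featured) + len(self.pending_unfeatured)

    @property
    def dr(self) -> float:
        """Drug-target ratio DR = |D| / |P|."""
        return self.n_targets / len(self.all_nodes)

    @property
    def pr(self) -> float:
        """Pending-test ratio PR = |PT| / |P|."""
        return self.n_pending / len(self.all_nodes)

    def label_of(self, node) -> str:
        if node in self.targets:
            return "D"
        if node in self.pending_featured:
            return "PT1"
        return "PT2"


def assign_labels(
    net: nx.Graph,
    target_ids: Iterable,
    featured_ids: Iterable = (),
) -> LabeledProteome:
    """Assign D / PT1 / PT2 labels to the nodes of *net*.

    Identifiers absent from the network are dropped (counted in the report
    fields).  Featured identifiers that are targets stay in D; PT1 is the
    featured remainder; PT2 is everything else.
    """
    nodes = set(net.nodes())
    targets = set(target_ids)
    featured = set(featured_ids)
    d = targets & nodes
    pt1 = (featured & nodes) - d
    pt2 = nodes - d - pt1
    if not d:
        warnings.warn(
            "no target identifiers matched the network; enrichment statistics "
            "will be undefined",
            stacklevel=2,
        )
    return LabeledProteome(
        targets=d,
        pending_featured=pt1,
        pending_unfeatured=pt2,
        dropped_targets=len(targets - nodes),
        dropped_featured=len(featured - nodes),
    )


def read_labels(path: str | Path) -> set:
    """Read a label file: one identifier per line, ``#`` comments allowed."""
    out = set()
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.add(line.split()[0])
    return out


@dataclass(frozen=True)
class FeatureLoadReport:
    n_rows: int = 0
    n_rejected: int = 0  # rows with missing / non-numeric values
    rejected_ids: tuple = ()


def read_feature_table(
    path: str | Path, expected_columns: int | None = None
) -> tuple[pd.DataFrame, FeatureLoadReport]:
    """Read a per-protein numeric feature table (TSV, first column = id).

    Rows with any missing or non-numeric value are rejected and reported.
    ``expected_columns`` (e.g. 39 chemical-physical properties) is enforced
    when given.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    if expected_columns is not None and df.shape[1] != expected_columns:
        raise ValueError(
            f"feature table has {df.shape[1]} columns, expected {expected_columns}"
        )
    bad = df.index[df.isna().any(axis=1)]
    report = FeatureLoadReport(
        n_rows=len(df), n_rejected=len(bad), rejected_ids=tuple(map(str, bad))
    )
    return df.drop(index=bad), report


def coverage_report(
    original: Mapping[str, int], used: Mapping[str, int]
) -> pd.DataFrame:
    """Coverage accounting: used counts over original counts, as percents.

    Returns one row per category with columns ``original``, ``used`` and
    ``coverage_pct`` (rounded to one decimal).  A category with original
    count 0 gets an absent (NaN) ratio.
    """
    rows = []
    for cat, orig in original.items():
        u = used.get(cat, 0)
        if u > orig:
            raise ValueError(f"category {cat!r}: used ({u}) exceeds original ({orig})")
        pct = round(100.0 * u / orig, 1) if orig > 0 else np.nan
        rows.append({"category": cat, "original": orig, "used": u, "coverage_pct": pct})
    return pd.DataFrame(rows).set_index("category")
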