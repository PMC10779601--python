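"""Background protein-protein interaction network.

The interactome is the undirected, simple graph over which every network
distance in the pipeline is measured.  Hop counts (unweighted shortest path
lengths) are the only metric: an edge means one experimentally supported
physical/functional interaction, and no confidence weighting is applied.

This module loads an edge list into a validated :class:`InteractomeGraph`,
extracts the largest connected component (the domain on which hop distances
are finite), runs multi-source breadth-first searches, and partitions nodes
into degree bins for the degree-preserving permutation null.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractomeGraph",
    "DegreeBin",
    "DegreeBins",
    "load_edge_list",
    "load_id_map",
    "write_edge_list",
    "largest_connected_component",
    "shortest_path_from_set",
    "build_degree_bins",
]


@dataclass
class InteractomeGraph:
    """Undirected simple graph of protein/gene nodes.

    Node identifiers are opaque, case-sensitive strings (whitespace-trimmed
    at load time).  Self-loops and duplicate edges are never present; the
    counts dropped during loading are retained so input provenance stays
    reportable.
    """

    graph: nx.Graph
    name: str = "interactome"
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"InteractomeGraph(name={self.name!r}, "
            f"n_nodes={self.n_nodes}, n_edges={self.n_edges})"
        )


def load_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column [from, to] TSV mapping of node identifiers."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: ID map rows need 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def load_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    id_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> InteractomeGraph:
    """Load an undirected simple graph from a two-column edge list.

    Parameters
    ----------
    path
        Text file with one interaction per row: ``node_a<sep>node_b``.
        Lines starting with ``#`` and blank lines are ignored; extra columns
        are ignored.
    delimiter
        Column separator; ``None`` splits on any whitespace (covers both TSV
        and space-separated files).
    id_map
        Optional identifier translation applied to both endpoints before
        validation (e.g. gene symbol -> UniProt entry name).  Identifiers
        absent from the map pass through unchanged.
    name
        Label for the returned graph; defaults to the file stem.

    Self-loop rows (``a<sep>a``) and duplicate edges are dropped, counted and
    logged, so input counts such as total interactions vs. retained edges are
    exactly reproducible.
    """
    path = Path(path)
    g = nx.Graph()
    n_self = 0
    n_dup = 0
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=2 columns, got "
                    f"{len(fields)}: {line!r}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValueError(
                    f"{path}: line {lineno}: empty node identifier"
                )
            if id_map is not None:
                a = id_map.get(a, a)
                b = id_map.get(b, b)
            n_rows += 1
            if a == b:
                n_self += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_rows == 0:
        raise ValueError(f"{path}: no edge rows found")
    ig = InteractomeGraph(
        graph=g,
        name=name if name is not None else path.stem,
        n_self_loops_dropped=n_self,
        n_duplicates_dropped=n_dup,
    )
    logger.info(
        "loaded %s: %d nodes, %d edges (%d self-loops dropped, %d duplicates "
        "dropped)",
        ig.name,
        ig.n_nodes,
        ig.n_edges,
        n_self,
        n_dup,
    )
    return ig


def write_edge_list(g: InteractomeGraph, path: str | Path) -> None:
    """Write the edge set as a sorted two-column TSV (deterministic order)."""
    edges = sorted(tuple(sorted(e)) for e in g.graph.edges)
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def largest_connected_component(g: InteractomeGraph) -> InteractomeGraph:
    """Induced subgraph on the largest connected component.

    Hop distances are undefined across components, so all proximity
    computation is restricted to the LCC.  Size ties are broken by the
    component containing the lexicographically smallest node, making the
    result deterministic.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot take the LCC of an empty graph")
    components = list(nx.connected_components(g.graph))
    max_size = max(len(c) for c in components)
    chosen = min(
        (c for c in components if len(c) == max_size),
        key=lambda c: min(c),
    )
    sub = g.graph.subgraph(chosen).copy()
    kept = len(chosen) / g.n_nodes
    logger.info(
        "LCC of %s: %d/%d nodes retained (%.1f%%)",
        g.name,
        len(chosen),
        g.n_nodes,
        100 * kept,
    )
    return InteractomeGraph(
        graph=sub,
        name=f"{g.name}:lcc",
        n_self_loops_dropped=g.n_self_loops_dropped,
        n_duplicates_dropped=g.n_duplicates_dropped,
    )


def shortest_path_from_set(
    g: InteractomeGraph, sources: Iterable[str]
) -> dict[str, int]:
    """Multi-source BFS hop distances from a set of seed nodes.

    Returns ``{node: min hop distance to any source}`` for every node
    reachable from at least one source; unreachable nodes are absent.
    """
    src = set(sources)
    missing = src - set(g.graph.nodes)
    if missing:
        raise ValueError(
            "source nodes not in graph: " + ", ".join(sorted(missing))
        )
    dist: dict[str, int] = {s: 0 for s in src}
    queue: deque[str] = deque(src)
    adj = g.graph.adj
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


@dataclass(frozen=True)
class DegreeBin:
    degree_min: int
    degree_max: int
    nodes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class DegreeBins:
    """Partition of graph nodes into contiguous-degree bins.

    Used by the degree-preserving null: a permuted stand-in for a node is
    drawn uniformly from that node's bin, so resampled sets preserve the
    degree profile of the original set up to bin resolution.  Every bin holds
    at least ``min_bin_size`` nodes (the trailing high-degree bin is merged
    downward until it does), because tiny bins would make the null nearly
    deterministic for hub nodes.
    """

    bins: list[DegreeBin]
    min_bin_size: int
    _node_to_bin: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._node_to_bin:
            for i, b in enumerate(self.bins):
                for node in b.nodes:
                    self._node_to_bin[node] = i

    def __len__(self) -> int:
        return len(self.bins)

    def bin_index_of(self, node: str) -> int:
        return self._node_to_bin[node]

    def bin_of(self, node: str) -> DegreeBin:
        return self.bins[self._node_to_bin[node]]

    @property
    def n_nodes(self) -> int:
        return sum(len(b) for b in self.bins)


def build_degree_bins(g: InteractomeGraph, min_bin_size: int = 100) -> DegreeBins:
    """Greedily group nodes into contiguous-degree bins of >= min_bin_size.

    Nodes are grouped by exact degree, degrees are walked in ascending order,
    and degree classes are accumulated until the running bin reaches
    ``min_bin_size`` (all nodes of equal degree always share a bin).  A
    trailing undersized bin is merged into its predecessor.  The result is
    deterministic for a given graph.
    """
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    if g.n_nodes == 0:
        raise ValueError("cannot bin an empty graph")
    if min_bin_size > g.n_nodes:
        logger.warning(
            "min_bin_size=%d exceeds node count %d; using a single bin",
            min_bin_size,
            g.n_nodes,
        )
    by_degree: dict[int, list[str]] = {}
    for node, deg in g.graph.degree:
        by_degree.setdefault(deg, []).append(node)
    bins: list[DegreeBin] = []
    cur_nodes: list[str] = []
    cur_min: int | None = None
    for deg in sorted(by_degree):
        if cur_min is None:
            cur_min = deg
        cur_nodes.extend(sorted(by_degree[deg]))
        if len(cur_nodes) >= min_bin_size:
            bins.append(DegreeBin(cur_min, deg, tuple(cur_nodes)))
            cur_nodes = []
            cur_min = None
    if cur_nodes:
        if bins:
            last = bins.pop()
            bins.append(
                DegreeBin(
                    last.degree_min,
                    max(by_degree),
                    last.nodes + tuple(cur_nodes),
                )
            )
        else:
            bins.append(DegreeBin(cur_min, max(by_degree), tuple(cur_nodes)))
    return DegreeBins(bins=bins, min_bin_size=min_bin_size)
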