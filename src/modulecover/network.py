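"""Undirected interaction networks: container type, file IO, node lists.

Interaction networks are simple undirected graphs whose nodes are gene (or
protein) identifiers.  Self-loops and edge direction carry no meaning in the
module-cover model and are dropped on input.  Supported dialects are SIF
(three whitespace-separated columns, interaction type ignored), two-column
TSV edge lists, and GraphML for Cytoscape interoperability.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import networkx as nx

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

_DIALECTS = ("sif", "tsv", "graphml")


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed."""


class InteractionNetwork:
    """A simple undirected graph over gene identifiers.

    Invariants: no self-loops, no duplicate edges (unordered pairs are
    unique), every edge endpoint is a node.  Backed by a :class:`networkx.Graph`
    exposed as :attr:`graph` for algorithms.
    """

    __slots__ = ("graph",)

    def __init__(self, graph: nx.Graph | None = None):
        g = nx.Graph()
        if graph is not None:
            if any(u == v for u, v in graph.edges()):
                raise ValueError("interaction networks must not contain self-loops")
            g.add_nodes_from(str(n) for n in graph.nodes())
            g.add_edges_from((str(u), str(v)) for u, v in graph.edges())
        self.graph = g

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        net = cls()
        net.graph.add_nodes_from(str(n) for n in nodes)
        for u, v in edges:
            net.add_edge(str(u), str(v))
        return net

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on node {u!r} not allowed")
        self.graph.add_edge(u, v)

    # -- views ------------------------------------------------------------

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(self.graph.nodes())

    @property
    def edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def neighbors(self, node: str) -> Iterator[str]:
        return self.graph.neighbors(node)

    def copy(self) -> "InteractionNetwork":
        new = InteractionNetwork()
        new.graph = self.graph.copy()
        return new

    def induced_subgraph(self, nodes: Iterable[str]) -> nx.Graph:
        return self.graph.subgraph(nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.node_ids == other.node_ids and self.edge_set == other.edge_set

    def __hash__(self):  # mutable container; identity hash like nx.Graph
        return id(self)

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def _open_maybe(source: Union[str, Path, IO[str]], mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def read_network(
    source: Union[str, Path, IO[str]], dialect: str = "sif"
) -> InteractionNetwork:
    """Read an interaction network from *source* in the given *dialect*.

    Self-loops are dropped with a warning, duplicate edges collapse to one.
    SIF lines are ``A <type> B`` (interaction type ignored; a line with a
    single column declares an isolated node); TSV lines are ``A<TAB>B``.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "graphml":
        g = nx.read_graphml(source)
        g = nx.Graph(g)  # collapse multi-edges / drop direction if present
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.warning("dropping %d self-loop(s) from GraphML input", len(loops))
            g.remove_edges_from(loops)
        net = InteractionNetwork()
        net.graph.add_nodes_from(str(n) for n in g.nodes())
        net.graph.add_edges_from((str(u), str(v)) for u, v in g.edges())
        if net.n_nodes == 0:
            raise NetworkParseError("empty network file")
        return net

    fh, close = _open_maybe(source)
    net = InteractionNetwork()
    n_lines = 0
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            n_lines += 1
            if dialect == "sif":
                fields = line.split()
                if len(fields) == 1:
                    net.graph.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise NetworkParseError(
                        f"line {lineno}: SIF line needs 'A <type> B', got {line!r}"
                    )
                u, targets = fields[0], fields[2:]
            else:  # tsv
                fields = line.split("\t")
                if len(fields) != 2 or not fields[0] or not fields[1]:
                    raise NetworkParseError(
                        f"line {lineno}: TSV edge line needs exactly two columns, got {line!r}"
                    )
                u, targets = fields[0], [fields[1]]
            for v in targets:
                if u == v:
                    logger.warning(
                        "line %d: dropping self-loop on %r (node kept)", lineno, u
                    )
                    net.graph.add_node(u)
                else:
                    net.graph.add_edge(u, v)
    finally:
        if close:
            fh.close()
    if n_lines == 0:
        raise NetworkParseError("empty network file")
    return net


def write_network(
    net: InteractionNetwork, dest: Union[str, Path, IO[str]], dialect: str = "sif"
) -> None:
    """Write *net* to *dest*; inverse of :func:`read_network` up to ordering."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "graphml":
        nx.write_graphml(net.graph, dest)
        return
    fh, close = _open_maybe(dest, "w")
    try:
        seen: set[str] = set()
        for u, v in sorted((sorted(e) for e in net.graph.edges()), key=tuple):
            seen.add(u)
            seen.add(v)
            if dialect == "sif":
                fh.write(f"{u} pp {v}\n")
            else:
                fh.write(f"{u}\t{v}\n")
        for node in sorted(net.node_ids - seen):
            if dialect == "sif":
                fh.write(f"{node}\n")
            else:
                # TSV has no isolated-node syntax; note and drop
                logger.warning("TSV dialect cannot encode isolated node %r", node)
    finally:
        if close:
            fh.close()


def read_gene_list(source: Union[str, Path, IO[str]]) -> frozenset[str]:
    """Read a gene list: one identifier per line, ``#`` starts a comment."""
    fh, close = _open_maybe(source)
    try:
        genes = set()
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                genes.add(line)
        return frozenset(genes)
    finally:
        if close:
            fh.close()


def apply_node_lists(
    network: InteractionNetwork,
    positive: Iterable[str] = (),
    negative: Iterable[str] = (),
) -> tuple[InteractionNetwork, frozenset[str]]:
    """Apply positive/negative gene lists to *network*.

    Negative-list nodes are removed with their incident edges (they are
    ignored by the analysis); positive-list nodes are returned as an
    annotation set so that activity computation treats them as active in
    every case (zero case exceptions).  Identifiers absent from the network
    are ignored with a warning.  A gene on both lists is an error.
    """
    pos = frozenset(str(g) for g in positive)
    neg = frozenset(str(g) for g in negative)
    both = pos & neg
    if both:
        raise ValueError(
            f"gene(s) on both positive and negative list: {sorted(both)}"
        )
    missing = (pos | neg) - network.node_ids
    if missing:
        logger.warning(
            "%d listed gene(s) absent from the network: %s",
            len(missing),
            sorted(missing)[:5],
        )
    out = network.copy()
    out.graph.remove_nodes_from(neg & network.node_ids)
    return out, frozenset(pos & out.node_ids)
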