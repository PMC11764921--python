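"""Signed directed networks and their SIF file I/O.

The central object is :class:`SignedNetwork`: a directed graph whose edges
carry a regulatory sign (+1 activation, -1 inhibition).  Prior-knowledge
networks (PKNs), mRNA signaling-regulatory networks, and the activated
subnetworks returned by the ILP are all instances of this type.

The on-disk format is a three-column SIF dialect::

    SOURCE  <relation>  TARGET

with relation one of ``1``/``activates`` (sign +1) or ``-1``/``inhibits``
(sign -1).  Plain SIF cannot express isolated nodes, so these are appended
on a trailing ``#nodes:`` comment line, which the parser understands; this
makes the parse/write round trip lossless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable

import networkx as nx

__all__ = [
    "Edge",
    "SignedNetwork",
    "NetworkStats",
    "SifParseError",
    "parse_sif",
    "write_sif",
    "network_stats",
]

#: (source, target, sign) with sign in {+1, -1}
Edge = tuple[str, str, int]

_RELATION_TOKENS = {"1": 1, "activates": 1, "-1": -1, "inhibits": -1}


class SifParseError(ValueError):
    """Raised when a SIF stream violates the three-column signed dialect."""


@dataclass(frozen=True)
class SignedNetwork:
    """A directed graph with signed edges.

    Parameters
    ----------
    nodes
        Node identifiers (HGNC-style gene symbols or protein labels).
    edges
        ``(source, target, sign)`` triples with ``sign`` in ``{+1, -1}``.
        Parallel edges with opposite signs are permitted (context-dependent
        dual regulation occurs in curated networks) but trigger a warning.
    """

    nodes: frozenset[str]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        seen: set[Edge] = set()
        pairs_by_sign: dict[tuple[str, str], set[int]] = {}
        for edge in self.edges:
            if len(edge) != 3:
                raise ValueError(f"edge must be a (source, target, sign) triple: {edge!r}")
            src, tgt, sign = edge
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {sign!r} on {src}->{tgt}")
            if src not in self.nodes or tgt not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: {edge!r}")
            if edge in seen:
                raise ValueError(f"duplicate edge: {edge!r}")
            seen.add(edge)
            pairs_by_sign.setdefault((src, tgt), set()).add(sign)
        dual = sorted(pair for pair, signs in pairs_by_sign.items() if len(signs) == 2)
        if dual:
            warnings.warn(
                f"network contains dual-sign edge pairs (activation and inhibition "
                f"between the same nodes): {dual}",
                stacklevel=3,
            )

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], extra_nodes: Iterable[str] = ()
    ) -> "SignedNetwork":
        """Build a network from an edge list, adding endpoints automatically."""
        edges = tuple(edges)
        nodes = {n for e in edges for n in e[:2]} | set(extra_nodes)
        return cls(nodes=frozenset(nodes), edges=edges)

    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self.edges)

    def predecessors(self, node: str) -> list[Edge]:
        """Incoming edges of *node*."""
        return [e for e in self.edges if e[1] == node]

    def successors(self, node: str) -> list[Edge]:
        """Outgoing edges of *node*."""
        return [e for e in self.edges if e[0] == node]

    def subnetwork(self, keep_nodes: Iterable[str]) -> "SignedNetwork":
        """Induced subgraph on *keep_nodes*."""
        keep = frozenset(keep_nodes)
        missing = keep - self.nodes
        if missing:
            raise KeyError(f"nodes not in network: {sorted(missing)}")
        edges = tuple(e for e in self.edges if e[0] in keep and e[1] in keep)
        return SignedNetwork(nodes=keep, edges=edges)

    def to_networkx(self) -> nx.MultiDiGraph:
        """Export as a :class:`networkx.MultiDiGraph` with a ``sign`` edge attribute."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for src, tgt, sign in self.edges:
            g.add_edge(src, tgt, sign=sign)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(self.edges) == set(other.edges)

    def __hash__(self) -> int:
        return hash((self.nodes, frozenset(self.edges)))


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_activating: int
    n_inhibiting: int

    def __post_init__(self) -> None:
        if self.n_edges != self.n_activating + self.n_inhibiting:
            raise ValueError("n_edges must equal n_activating + n_inhibiting")


def parse_sif(stream: str | IO[str] | Iterable[str]) -> SignedNetwork:
    """Parse the three-column signed SIF dialect.

    Accepts a string, an open text file, or any iterable of lines.  Lines are
    whitespace- or tab-separated ``source relation target`` triples; blank
    lines are skipped; a ``#nodes:`` comment line lists isolated nodes; other
    ``#`` comment lines are ignored.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream
    edges: list[Edge] = []
    extra_nodes: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("nodes:"):
                extra_nodes.extend(body[len("nodes:"):].split())
            continue
        fields = line.split()
        if len(fields) != 3:
            raise SifParseError(
                f"line {lineno}: expected 3 fields (source relation target), "
                f"got {len(fields)}: {line!r}"
            )
        src, relation, tgt = fields
        if relation not in _RELATION_TOKENS:
            raise SifParseError(
                f"line {lineno}: unknown relation {relation!r} "
                f"(expected one of {sorted(_RELATION_TOKENS)})"
            )
        edges.append((src, tgt, _RELATION_TOKENS[relation]))
    return SignedNetwork.from_edges(edges, extra_nodes=extra_nodes)


def write_sif(network: SignedNetwork) -> str:
    """Serialize a network to the signed SIF dialect.

    Edges are emitted in sorted order; isolated nodes go into a trailing
    ``#nodes:`` comment so that ``parse_sif(write_sif(n)) == n``.
    """
    out = [f"{src}\t{sign}\t{tgt}" for src, tgt, sign in sorted(network.edges)]
    connected = {n for e in network.edges for n in e[:2]}
    isolated = sorted(network.nodes - connected)
    if isolated:
        out.append("#nodes: " + " ".join(isolated))
    return "\n".join(out) + ("\n" if out else "")


def network_stats(network: SignedNetwork) -> NetworkStats:
    """Count nodes and edges by sign."""
    n_act = sum(1 for e in network.edges if e[2] == 1)
    return NetworkStats(
        n_nodes=len(network.nodes),
        n_edges=len(network.edges),
        n_activating=n_act,
        n_inhibiting=len(network.edges) - n_act,
    )
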