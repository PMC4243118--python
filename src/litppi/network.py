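"""Protein–protein interaction networks: data model, I/O and graph primitives.

A PPI network is an undirected graph whose vertices are protein identifiers
(by convention systematic yeast ORF names such as ``YAL001C``, though any
whitespace-free token is accepted) and whose edges are interactions, optionally
carrying a real-valued reliability weight.  This module provides the edge-list
reader/writer, the hygiene filter that drops self-interactions and isolated
proteins, and the two graph quantities the detection stage relies on: complex
*density* and network *transitivity*.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "read_network",
    "write_network",
    "filter_self_and_isolated",
    "density",
    "transitivity",
    "canonical_pair",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair ``(a, b)`` in lexicographic order."""
    return (a, b) if a <= b else (b, a)


class PPINetwork:
    """An undirected PPI network backed by a :class:`networkx.Graph`.

    Parameters
    ----------
    graph
        Undirected graph; when ``weighted`` is true every edge must carry a
        finite ``weight`` attribute.
    weighted
        Whether edges carry reliability weights.  Unweighted networks never
        store a ``weight`` attribute; density then counts one per edge.
    """

    def __init__(self, graph: nx.Graph | None = None, weighted: bool = False):
        self.graph = graph if graph is not None else nx.Graph()
        self.weighted = bool(weighted)
        self._validate()

    def _validate(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if self.weighted:
                w = data.get("weight")
                if w is None or not math.isfinite(w):
                    raise ValueError(f"edge {u}-{v}: weighted network requires a finite weight")
            elif "weight" in data:
                raise ValueError(f"edge {u}-{v}: unweighted network must not carry weights")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        weighted: bool = False,
        proteins: Iterable[str] = (),
    ) -> "PPINetwork":
        """Build a network from ``(a, b)`` or ``(a, b, weight)`` tuples.

        Duplicate unordered pairs resolve first-wins.  ``proteins`` may list
        additional vertices (e.g. isolated ones) to include.
        """
        g = nx.Graph()
        g.add_nodes_from(proteins)
        for edge in edges:
            if weighted:
                a, b, w = edge
            else:
                a, b = edge[0], edge[1]
            a, b = canonical_pair(str(a), str(b))
            if g.has_edge(a, b):
                continue
            if weighted:
                g.add_edge(a, b, weight=float(w))
            else:
                g.add_edge(a, b)
        return cls(g, weighted=weighted)

    # -- basic protocol -------------------------------------------------------

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, a: str, b: str) -> float:
        """Weight of edge a-b; 1.0 in an unweighted network; KeyError if absent."""
        if not self.graph.has_edge(a, b):
            raise KeyError(f"no edge {a}-{b}")
        return float(self.graph.edges[a, b].get("weight", 1.0))

    def edges(self) -> list[tuple[str, str, float]]:
        """All edges as canonicalized ``(a, b, weight)`` triples, sorted."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = canonical_pair(u, v)
            out.append((a, b, float(data.get("weight", 1.0))))
        return sorted(out)

    def copy(self) -> "PPINetwork":
        return PPINetwork(self.graph.copy(), weighted=self.weighted)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return (
            self.weighted == other.weighted
            and self.proteins == other.proteins
            and self.edges() == other.edges()
        )

    def __repr__(self) -> str:
        kind = "weighted" if self.weighted else "unweighted"
        return f"<PPINetwork {kind}: {self.n_proteins} proteins, {self.n_edges} interactions>"


def read_network(path: str | Path, weighted: bool = False) -> PPINetwork:
    """Read a tab-separated edge list into a :class:`PPINetwork`.

    The dialect is two columns ``protein_a<TAB>protein_b`` (unweighted) or
    three columns with a trailing weight.  Lines starting with ``#`` and blank
    lines are skipped.  Duplicate unordered pairs keep the first occurrence;
    later ones are logged and dropped.  Self-loops are retained here — hygiene
    is a separate, explicit step (:func:`filter_self_and_isolated`).

    Raises
    ------
    ValueError
        On a malformed line (wrong column count, non-numeric weight), naming
        the offending line number.
    """
    path = Path(path)
    g = nx.Graph()
    n_dup = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if weighted:
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: weighted network requires 3 columns, got {len(fields)}"
                    )
                a, b, wtext = fields[0].strip(), fields[1].strip(), fields[2].strip()
                try:
                    w = float(wtext)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: weight {wtext!r} is not a number") from None
                if not math.isfinite(w):
                    raise ValueError(f"{path}:{lineno}: weight must be finite")
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}")
                a, b = fields[0].strip(), fields[1].strip()
                w = None
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty protein identifier")
            a, b = canonical_pair(a, b)
            if g.has_edge(a, b):
                n_dup += 1
                logger.warning("%s:%d: duplicate pair %s-%s ignored (first occurrence kept)", path, lineno, a, b)
                continue
            if weighted:
                g.add_edge(a, b, weight=w)
            else:
                g.add_edge(a, b)
    if n_dup:
        logger.info("%s: dropped %d duplicate pairs", path, n_dup)
    return PPINetwork(g, weighted=weighted)


def write_network(net: PPINetwork, path: str | Path) -> None:
    """Write a canonicalized (sorted-pair) edge list with a header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# weighted={str(net.weighted).lower()}\n")
        for a, b, w in net.edges():
            if net.weighted:
                fh.write(f"{a}\t{b}\t{w:.17g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def filter_self_and_isolated(net: PPINetwork) -> PPINetwork:
    """Drop self-interactions, then proteins left without any interaction.

    Idempotent; never adds proteins or edges.
    """
    g = net.graph.copy()
    g.remove_edges_from(list(nx.selfloop_edges(g)))
    g.remove_nodes_from([n for n, d in g.degree() if d == 0])
    return PPINetwork(g, weighted=net.weighted)


def density(net: PPINetwork, members: Iterable[str]) -> float:
    """Density of a candidate complex: internal edge weight over possible pairs.

    For a member set of size n the density is the total weight of edges with
    both endpoints in the set, divided by n(n-1)/2.  In an unweighted network
    each internal edge counts 1, so the value lies in [0, 1]; with weights
    above 1 the ratio can exceed 1 and is deliberately not clamped.

    Raises
    ------
    ValueError
        If fewer than 2 members, or a member is not in the network.
    """
    members = set(members)
    if len(members) < 2:
        raise ValueError("density needs at least 2 members (n(n-1)/2 would be 0)")
    missing = members - net.proteins
    if missing:
        raise ValueError(f"members not in network: {sorted(missing)[:5]}")
    sub = net.graph.subgraph(members)
    total = sum(data.get("weight", 1.0) for _, _, data in sub.edges(data=True))
    n = len(members)
    return total / (n * (n - 1) / 2)


def transitivity(net: PPINetwork) -> float:
    """Global clustering coefficient: 3 x triangles / connected triples.

    Computed on the unweighted topology regardless of edge weights.  A network
    with no connected triples has undefined transitivity; 0 is returned with a
    warning so the auto density-threshold rule still resolves.
    """
    t = nx.transitivity(net.graph)
    if t == 0 and not any(d >= 2 for _, d in net.graph.degree()):
        logger.warning("network has no connected triples; transitivity reported as 0")
    return float(t)
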