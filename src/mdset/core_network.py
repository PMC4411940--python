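"""Data model and file I/O for protein interaction networks and annotations.

A binary protein interaction network is an undirected simple graph
``G = (V, E)`` over opaque protein identifiers. Companion inputs are an
essential-gene list (one identifier per line), a protein-complex catalog
(complex -> member sets, overlaps allowed) and a functional-class annotation
(protein -> one or more single-letter class codes, COG style).

Identifiers are case-sensitive strings and no symbol mapping is attempted;
mismatched namespaces simply surface as low overlap downstream. Self-loops
and duplicate/reversed edges are dropped on read, with counts logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ProteinNetwork",
    "GeneSet",
    "ComplexCatalog",
    "ClassAnnotation",
    "NetworkSummary",
    "read_edge_list",
    "read_gene_set",
    "read_complex_catalog",
    "read_class_annotation",
    "write_edge_list",
    "write_gene_set",
    "write_complex_catalog",
    "write_class_annotation",
    "network_summary",
    "connected_components",
]


class ParseError(ValueError):
    """Raised when an input file does not match its declared dialect."""


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


class ProteinNetwork:
    """Undirected simple graph over protein identifiers.

    Construction normalizes the edge list: self-loops are discarded and
    duplicate or reversed pairs collapse to a single undirected edge. Both
    endpoints of every edge are nodes; isolated nodes are permitted.

    Parameters
    ----------
    edges
        Iterable of identifier pairs.
    nodes
        Extra identifiers to include even if they touch no edge.
    name
        Free-text label used in logs and reports.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        name: str = "",
    ) -> None:
        self.name = name
        self._adj: dict[str, set[str]] = {str(v): set() for v in nodes}
        self.n_self_loops_dropped = 0
        self.n_duplicates_merged = 0
        seen: set[tuple[str, str]] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                self.n_self_loops_dropped += 1
                self._adj.setdefault(u, set())
                continue
            key = (u, v) if u < v else (v, u)
            if key in seen:
                self.n_duplicates_merged += 1
                continue
            seen.add(key)
            self._adj.setdefault(u, set()).add(v)
            self._adj.setdefault(v, set()).add(u)
        self._nx: nx.Graph | None = None

    # -- basic queries ----------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def node_order(self) -> list[str]:
        """Deterministic (sorted) node order used for all tie-breaking."""
        return sorted(self._adj)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {
            (u, v) for u in self._adj for v in self._adj[u] if u < v
        }

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def __contains__(self, v: str) -> bool:
        return v in self._adj

    def neighbors(self, v: str) -> set[str]:
        """Interaction partners Γ(v)."""
        return set(self._adj[v])

    def degree(self, v: str) -> int:
        return len(self._adj[v])

    def degrees(self) -> dict[str, int]:
        return {v: len(nbrs) for v, nbrs in self._adj.items()}

    def to_networkx(self) -> nx.Graph:
        """networkx view (cached); includes isolated nodes."""
        if self._nx is None:
            g = nx.Graph(name=self.name)
            g.add_nodes_from(self.node_order)
            g.add_edges_from(sorted(self.edges))
            self._nx = g
        return self._nx

    def subgraph_without(self, removed: Iterable[str]) -> "ProteinNetwork":
        removed = set(removed)
        keep = [v for v in self._adj if v not in removed]
        edges = [
            (u, v)
            for u, v in self.edges
            if u not in removed and v not in removed
        ]
        return ProteinNetwork(edges, nodes=keep, name=self.name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = f" {self.name!r}" if self.name else ""
        return f"<ProteinNetwork{label}: {self.n_nodes} nodes, {self.n_edges} edges>"


@dataclass(frozen=True)
class GeneSet:
    """A labeled set of protein identifiers (e.g. essential genes).

    Members may be absent from a given network; every analysis intersects
    the set with the network's nodes explicitly.
    """

    members: frozenset[str]
    label: str = ""

    def in_network(self, net: ProteinNetwork) -> set[str]:
        return self.members & net.nodes

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ComplexCatalog:
    """Named protein complexes; a protein may belong to several."""

    complexes: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {cid!r} has no members")

    @property
    def n_complexes(self) -> int:
        """N, the total number of complexes."""
        return len(self.complexes)

    def membership(self) -> dict[str, set[str]]:
        """protein -> set of complex identifiers it belongs to."""
        out: dict[str, set[str]] = {}
        for cid, members in self.complexes.items():
            for p in members:
                out.setdefault(p, set()).add(cid)
        return out

    def proteins(self) -> set[str]:
        return set().union(*self.complexes.values()) if self.complexes else set()


@dataclass(frozen=True)
class ClassAnnotation:
    """Protein -> nonempty set of single-character functional class codes."""

    assignments: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for p, codes in self.assignments.items():
            if not codes:
                raise ValueError(f"protein {p!r} has an empty class assignment")
            for c in codes:
                if len(c) != 1:
                    raise ValueError(f"class code {c!r} is not a single character")

    @property
    def alphabet(self) -> set[str]:
        return set().union(*self.assignments.values()) if self.assignments else set()


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    mean_degree: float


# -- readers --------------------------------------------------------------


def read_edge_list(path: str | Path, dialect: str = "tsv-2col") -> ProteinNetwork:
    """Read a network from a two-column edge list or a SIF file.

    ``tsv-2col`` lines name two identifiers; ``sif`` lines are
    node / relation / node with the relation ignored. Normalization drops
    self-loops and merges duplicate or reversed pairs, logging the counts.
    Raises :class:`ParseError` on malformed lines and on an empty file.
    """
    if dialect not in ("tsv-2col", "sif"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if dialect == "tsv-2col":
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
        else:
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 SIF columns, got {len(fields)}"
                )
            edges.append((fields[0], fields[2]))
    if not edges:
        raise ParseError(f"{path}: empty edge list")
    net = ProteinNetwork(edges, name=str(Path(path).name))
    if net.n_self_loops_dropped or net.n_duplicates_merged:
        logger.info(
            "%s: dropped %d self-loop(s), merged %d duplicate edge(s)",
            path,
            net.n_self_loops_dropped,
            net.n_duplicates_merged,
        )
    return net


def read_gene_set(path: str | Path, label: str = "") -> GeneSet:
    """Read one identifier per line; duplicates collapse, empty set warns."""
    members: set[str] = set()
    n_lines = 0
    for _, line in _data_lines(path):
        members.add(line.split()[0])
        n_lines += 1
    if not members:
        logger.warning("%s: empty gene set", path)
    else:
        logger.info("%s: %d unique members from %d lines", path, len(members), n_lines)
    return GeneSet(frozenset(members), label=label or str(Path(path).stem))


def read_complex_catalog(path: str | Path, dialect: str = "long") -> ComplexCatalog:
    """Read a complex catalog.

    ``long``: one (complex_id, member) row per line. ``wide``: complex_id
    followed by semicolon-joined members. Overlapping membership is
    preserved; a complex that ends up empty is an error.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown complex-catalog dialect {dialect!r}")
    complexes: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        cid, payload = fields
        if dialect == "long":
            complexes.setdefault(cid, set()).add(payload)
        else:
            members = {m for m in payload.split(";") if m}
            if not members:
                raise ParseError(f"{path}:{lineno}: complex {cid!r} has no members")
            complexes.setdefault(cid, set()).update(members)
    if not complexes:
        raise ParseError(f"{path}: empty complex catalog")
    return ComplexCatalog({cid: frozenset(m) for cid, m in complexes.items()})


def read_class_annotation(path: str | Path) -> ClassAnnotation:
    """Read protein<TAB>codes rows, codes concatenated (e.g. ``KLT``)."""
    assignments: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        protein, codes = fields
        assignments.setdefault(protein, set()).update(codes)
    return ClassAnnotation({p: frozenset(c) for p, c in assignments.items()})


# -- writers (round-trip counterparts, also used by the study generator) --


def write_edge_list(net: ProteinNetwork, path: str | Path, dialect: str = "tsv-2col") -> None:
    if dialect not in ("tsv-2col", "sif"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            if dialect == "tsv-2col":
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\tpp\t{v}\n")


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes.members):
            fh.write(g + "\n")


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path, dialect: str = "long") -> None:
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown complex-catalog dialect {dialect!r}")
    with open(path, "w") as fh:
        for cid in sorted(catalog.complexes):
            members = sorted(catalog.complexes[cid])
            if dialect == "long":
                for m in members:
                    fh.write(f"{cid}\t{m}\n")
            else:
                fh.write(f"{cid}\t{';'.join(members)}\n")


def write_class_annotation(annotation: ClassAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(annotation.assignments):
            fh.write(f"{p}\t{''.join(sorted(annotation.assignments[p]))}\n")


# -- graph queries --------------------------------------------------------


def network_summary(net: ProteinNetwork) -> NetworkSummary:
    """Node/edge counts and mean degree 2|E|/|V| (interactions per protein)."""
    if net.n_nodes == 0:
        raise ValueError("cannot summarize an empty network")
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_degree=2.0 * net.n_edges / net.n_nodes,
    )


def connected_components(net: ProteinNetwork) -> list[set[str]]:
    """Partition of nodes into connected components; isolates are singletons."""
    return [set(c) for c in nx.connected_components(net.to_networkx())]
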