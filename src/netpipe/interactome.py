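"""Undirected protein–protein interaction graph: data model, file I/O, subgraphs.

The interactome is a simple undirected graph over HGNC-style gene symbols.
Symbols are normalized (whitespace-trimmed, upper-cased) on entry so that
lists coming from different expression platforms match the graph. Self-loops
are dropped (centrality definitions downstream assume a simple graph) and
duplicate edges in either orientation are collapsed; both events are counted
in the log rather than raised, because partial coverage between an array and
an interaction database is the norm, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "normalize_symbol",
    "GeneList",
    "Interactome",
    "read_edge_list",
    "write_graph",
    "induced_subgraph",
    "unmapped_symbols",
]


def normalize_symbol(symbol: str) -> str:
    """Trim whitespace and case-fold a gene symbol to upper case (idempotent)."""
    return symbol.strip().upper()


@dataclass
class GeneList:
    """An ordered, deduplicated list of gene symbols with a free-text label."""

    symbols: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        out: list[str] = []
        for s in self.symbols:
            s = normalize_symbol(str(s))
            if s and s not in seen:
                seen.add(s)
                out.append(s)
        self.symbols = out

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.as_set

    @property
    def as_set(self) -> set[str]:
        return set(self.symbols)

    @classmethod
    def from_file(cls, path: str | Path, label: str = "") -> "GeneList":
        """Read one symbol per line; blank lines and '#' comments are skipped."""
        lines = Path(path).read_text().splitlines()
        symbols = [ln for ln in (s.strip() for s in lines) if ln and not ln.startswith("#")]
        return cls(symbols, label=label or Path(path).stem)


@dataclass
class Interactome:
    """Simple undirected graph over normalized gene symbols.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node, at least one node.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: str = ""

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        provenance: str = "",
    ) -> "Interactome":
        """Build from an edge iterable, normalizing symbols and dropping
        self-loops / duplicates (counts logged)."""
        g = nx.Graph()
        n_self = 0
        n_dup = 0
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if not a or not b:
                raise ValueError(f"empty gene symbol in edge ({a!r}, {b!r})")
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
        for n in nodes:
            g.add_node(normalize_symbol(n))
        if n_self or n_dup:
            log.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
        return cls(graph=g, provenance=provenance)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as sorted 2-tuples (orientation-free canonical form)."""
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("interactome must contain at least one node")
        if any(a == b for a, b in self.graph.edges):
            raise ValueError("interactome contains self-loops")


def _iter_rows(path: Path) -> Iterator[tuple[int, list[str]]]:
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty edge-list file")
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield i, line.split("\t") if "\t" in line else line.split()


def read_edge_list(path: str | Path, format: str | None = None) -> Interactome:
    """Read an interactome from a SIF or 2-column TSV edge list.

    SIF rows are ``source<tab>relation<tab>target [target2 ...]``; TSV rows are
    ``source<tab>target``. A malformed row raises with its line number.
    """
    path = Path(path)
    fmt = format or ("sif" if path.suffix.lower() == ".sif" else "tsv")
    if fmt not in ("sif", "tsv"):
        raise ValueError(f"unknown edge-list format {fmt!r}")
    edges: list[tuple[str, str]] = []
    for lineno, fields in _iter_rows(path):
        if fmt == "tsv":
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
            edges.append((fields[0], fields[1]))
        else:  # sif: node relation target+
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: SIF row needs source, relation and >=1 target"
                )
            src = fields[0]
            for tgt in fields[2:]:
                edges.append((src, tgt))
    return Interactome.from_edges(edges, provenance=str(path))


def write_graph(
    g: Interactome,
    path: str | Path,
    format: str = "sif",
    node_attributes: dict[str, dict[str, object]] | None = None,
    relation: str = "pp",
) -> None:
    """Write the graph as SIF, 2-column TSV, or GraphML.

    SIF/TSV round-trip exactly through :func:`read_edge_list`. GraphML can
    carry per-node attributes (e.g. degree, betweenness, hub flags) via
    ``node_attributes`` keyed ``{node: {attr: value}}``.
    """
    path = Path(path)
    edges = sorted(g.edges)
    if format == "sif":
        path.write_text("".join(f"{a}\t{relation}\t{b}\n" for a, b in edges))
    elif format == "tsv":
        path.write_text("".join(f"{a}\t{b}\n" for a, b in edges))
    elif format == "graphml":
        out = g.graph.copy()
        if node_attributes:
            for node, attrs in node_attributes.items():
                if node in out:
                    out.nodes[node].update(attrs)
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown output format {format!r}")


def induced_subgraph(g: Interactome, genes: GeneList) -> Interactome:
    """Subgraph induced by ``genes`` ∩ graph nodes; unmapped count is logged.

    Unmapped list symbols are never fatal (interactome coverage is partial);
    use :func:`unmapped_symbols` to retrieve them.
    """
    keep = genes.as_set & g.nodes
    missing = len(genes) - len(keep)
    if missing:
        log.info("%d/%d list symbols absent from the interactome", missing, len(genes))
    sub = nx.Graph(g.graph.subgraph(keep))
    sub.add_nodes_from(keep)
    return Interactome(graph=sub, provenance=g.provenance)


def unmapped_symbols(g: Interactome, genes: GeneList) -> list[str]:
    """List symbols (input order) that do not appear in the interactome."""
    nodes = g.nodes
    return [s for s in genes if s not in nodes]
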