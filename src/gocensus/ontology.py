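"""Gene Ontology graphs and extraction of terminal molecular-function terms.

The ontology is held as a directed acyclic graph whose edges point from a
child term to its ``is_a`` parents.  Only ``is_a`` edges are loaded: they form
the backbone hierarchy of the ontology, and "terminal" (leaf) terms are
defined with respect to that backbone alone.  Other relationship types
(``part_of``, ``regulates``, ...) are deliberately ignored.
"""

from __future__ import annotations

import io
from typing import IO, Iterable

import networkx as nx
import obonet

MOLECULAR_FUNCTION = "molecular_function"
NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


class OboParseError(ValueError):
    """Raised when an OBO stream cannot be parsed; carries the line number."""


class GoGraph:
    """A GO term DAG restricted to ``is_a`` edges (child -> parent).

    Nodes carry ``name``, ``namespace`` and ``obsolete`` attributes.  Obsolete
    terms are retained but flagged; they never participate in leafness.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_term(self, term_id: str, name: str, namespace: str,
                 obsolete: bool = False) -> None:
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r} for {term_id}")
        if term_id in self._g:
            raise ValueError(f"duplicate term id {term_id}")
        self._g.add_node(term_id, name=name, namespace=namespace,
                         obsolete=bool(obsolete))

    def add_is_a(self, child: str, parent: str) -> None:
        for t in (child, parent):
            if t not in self._g:
                raise KeyError(f"unknown term {t}")
        self._g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._g):
            self._g.remove_edge(child, parent)
            raise ValueError(f"edge {child} is_a {parent} would create a cycle")

    # -- queries ----------------------------------------------------------
    @property
    def nx_graph(self) -> nx.DiGraph:
        return self._g

    def terms(self) -> list[str]:
        return sorted(self._g.nodes)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def name(self, term_id: str) -> str:
        return self._g.nodes[term_id]["name"]

    def namespace(self, term_id: str) -> str:
        return self._g.nodes[term_id]["namespace"]

    def is_obsolete(self, term_id: str) -> bool:
        return bool(self._g.nodes[term_id]["obsolete"])

    def parents(self, term_id: str) -> list[str]:
        return sorted(self._g.successors(term_id))

    def children(self, term_id: str) -> list[str]:
        return sorted(self._g.predecessors(term_id))

    def edges(self) -> list[tuple[str, str]]:
        """Sorted (child, parent) ``is_a`` pairs."""
        return sorted(self._g.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GoGraph):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        if set(self._g.edges) != set(other._g.edges):
            return False
        for n in self._g.nodes:
            a, b = self._g.nodes[n], other._g.nodes[n]
            if (a["name"], a["namespace"], a["obsolete"]) != \
               (b["name"], b["namespace"], b["obsolete"]):
                return False
        return True

    __hash__ = None  # mutable


def _prevalidate_obo(text: str) -> None:
    """Cheap line-level structure check so errors can name the line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("!"):
            continue
        if s.startswith("["):
            if not s.endswith("]"):
                raise OboParseError(f"line {lineno}: unterminated stanza header: {s!r}")
            continue
        if ":" not in s:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {s!r}")


def parse_obo(source: str | IO[str]) -> GoGraph:
    """Parse OBO 1.2 text into a :class:`GoGraph`.

    Only ``is_a`` edges are loaded.  Obsolete terms are kept and flagged.
    Terms without an explicit namespace raise an error.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    _prevalidate_obo(text)
    try:
        multi = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - defensive
        raise OboParseError(f"obonet failed to parse stream: {exc}") from exc

    graph = GoGraph()
    for node, data in multi.nodes(data=True):
        namespace = data.get("namespace")
        if namespace is None:
            raise OboParseError(f"term {node} has no namespace")
        graph.add_term(node, data.get("name", node), namespace,
                       obsolete=str(data.get("is_obsolete", "false")).lower() == "true")
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_is_a(child, parent)
    return graph


def terminal_mf_terms(graph: GoGraph) -> set[str]:
    """Terminal (leaf) terms of the molecular_function hierarchy.

    A term is terminal when it is a non-obsolete molecular_function term with
    no incoming ``is_a`` edge from another non-obsolete molecular_function
    term.  Equivalently: the complement, within non-obsolete MF terms, of the
    set of ``is_a`` parents of non-obsolete MF terms.
    """
    if len(graph) == 0:
        raise ValueError("empty ontology")
    mf = {t for t in graph.terms()
          if graph.namespace(t) == MOLECULAR_FUNCTION and not graph.is_obsolete(t)}
    if not mf:
        raise ValueError("ontology has no molecular_function namespace")
    parents_of_mf = {p for c in mf for p in graph.parents(c) if p in mf}
    return mf - parents_of_mf


def write_obo(graph: GoGraph, path_or_stream, header_date: str = "01:01:2009") -> None:
    """Serialize a :class:`GoGraph` to OBO 1.2 text (is_a edges only)."""
    own = not hasattr(path_or_stream, "write")
    fh = open(path_or_stream, "w") if own else path_or_stream
    try:
        fh.write("format-version: 1.2\n")
        fh.write(f"date: {header_date} 00:00\n")
        fh.write("ontology: go\n")
        for term in graph.terms():
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {graph.name(term)}\n")
            fh.write(f"namespace: {graph.namespace(term)}\n")
            if graph.is_obsolete(term):
                fh.write("is_obsolete: true\n")
            for parent in graph.parents(term):
                fh.write(f"is_a: {parent} ! {graph.name(parent)}\n")
    finally:
        if own:
            fh.close()


def obo_text(graph: GoGraph) -> str:
    buf = io.StringIO()
    write_obo(graph, buf)
    return buf.getvalue()


def make_go_graph(terms: Iterable[tuple[str, str, str]],
                  edges: Iterable[tuple[str, str]],
                  obsolete: Iterable[str] = ()) -> GoGraph:
    """Convenience constructor from (id, name, namespace) triples and edges."""
    obsolete = set(obsolete)
    g = GoGraph()
    for tid, name, ns in terms:
        g.add_term(tid, name, ns, obsolete=tid in obsolete)
    for child, parent in edges:
        g.add_is_a(child, parent)
    return g
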