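"""Ontology loading: OBO parsing into a validated directed acyclic graph.

Terms are nodes; edges run child -> parent and carry a ``relation``
attribute, either ``is_a`` or ``part_of``.  Only these two relation types
are traversed anywhere in the package (they are the ones the Wang measure
defines weights for); other relationship types present in an OBO file are
ignored.  Obsolete terms are dropped at parse time, and alternate
identifiers are recorded so that annotation files using superseded ids can
be resolved to the primary term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: The three GO aspects (namespaces).
ASPECTS = frozenset(
    {"biological_process", "molecular_function", "cellular_component"}
)

#: Relation types traversed for propagation, ancestors and Wang S-values.
TRAVERSED_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Raised when an ontology file violates a structural invariant."""


@dataclass
class OntologyGraph:
    """A DAG of ontology terms with typed child->parent edges.

    Attributes
    ----------
    graph : networkx.DiGraph
        Edges point from child to parent; each edge has a ``relation``
        attribute in ``{"is_a", "part_of"}``.
    namespace_of : dict
        Term id -> aspect label (e.g. ``"biological_process"``).
    roots : dict
        Aspect label -> the single parentless term of that namespace.
    alt_id_map : dict
        Alternate term id -> primary term id.
    """

    graph: nx.DiGraph
    namespace_of: dict[str, str]
    roots: dict[str, str]
    alt_id_map: dict[str, str] = field(default_factory=dict)

    # -- basic queries -----------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def resolve(self, term: str) -> str:
        """Map an alternate id to its primary id (identity otherwise)."""
        return self.alt_id_map.get(term, term)

    def namespace(self, term: str) -> str:
        return self.namespace_of[term]

    def parents(self, term: str) -> Iterator[str]:
        return self.graph.successors(term)

    def children(self, term: str) -> Iterator[str]:
        return self.graph.predecessors(term)

    def relation(self, child: str, parent: str) -> str:
        return self.graph.edges[child, parent]["relation"]

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """All terms reachable from ``term`` via is_a/part_of edges.

        The true-path rule treats a term as implicitly subsumed by all of
        its ancestors; by convention here the ancestor set includes the
        term itself when ``include_self`` (the default), which is the
        convention MICA computation requires.
        """
        # Edges point child -> parent, so graph-descendants are ancestors.
        anc = nx.descendants(self.graph, term)
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str, include_self: bool = True) -> set[str]:
        dec = nx.ancestors(self.graph, term)
        if include_self:
            dec.add(term)
        return dec

    def validate(self) -> None:
        """Check structural invariants; raise :class:`OntologyError` if violated."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"ontology graph contains a cycle: {path}")
        root_set = set(self.roots.values())
        for term in self.graph.nodes:
            if term in root_set:
                continue
            if self.graph.out_degree(term) == 0:
                raise OntologyError(
                    f"non-root term {term} ({self.namespace_of.get(term)}) "
                    "has no is_a/part_of parent"
                )
        for alt, primary in self.alt_id_map.items():
            if primary not in self.graph:
                raise OntologyError(
                    f"alt_id {alt} maps to unknown term {primary}"
                )


def load_obo(source: str | IO[str]) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into a validated :class:`OntologyGraph`.

    Parameters
    ----------
    source : path or file-like
        OBO document.  Obsolete terms are skipped; ``is_a`` and
        ``relationship: part_of`` lines become typed edges; any other
        relationship type is ignored.

    Raises
    ------
    OntologyError
        If the resulting graph is cyclic or a namespace lacks a unique
        root term.
    OSError
        If the file cannot be read.
    """
    multi = obonet.read_obo(source)  # drops obsolete stanzas

    default_ns = multi.graph.get("default-namespace", ["biological_process"])
    if isinstance(default_ns, list):
        default_ns = default_ns[0]

    graph = nx.DiGraph()
    namespace_of: dict[str, str] = {}
    alt_id_map: dict[str, str] = {}

    for term, data in multi.nodes(data=True):
        graph.add_node(term)
        namespace_of[term] = data.get("namespace", default_ns)
        for alt in data.get("alt_id", []):
            alt_id_map[alt] = term

    n_ignored = 0
    for child, parent, relation in multi.edges(keys=True):
        if relation not in TRAVERSED_RELATIONS:
            n_ignored += 1
            continue
        if graph.has_edge(child, parent):
            # is_a takes precedence if a pair is related both ways
            if graph.edges[child, parent]["relation"] == "is_a":
                continue
        graph.add_edge(child, parent, relation=relation)
    if n_ignored:
        logger.info("ignored %d edges of non-traversed relation types", n_ignored)

    roots = _find_roots(graph, namespace_of)
    onto = OntologyGraph(
        graph=graph,
        namespace_of=namespace_of,
        roots=roots,
        alt_id_map=alt_id_map,
    )
    onto.validate()
    logger.info(
        "loaded ontology: %d terms, %d edges, namespaces %s",
        len(onto), graph.number_of_edges(), sorted(roots),
    )
    return onto


def _find_roots(
    graph: nx.DiGraph, namespace_of: dict[str, str]
) -> dict[str, str]:
    """One parentless term per namespace; more or fewer is an error."""
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyError(f"ontology graph contains a cycle: {path}")
    parentless: dict[str, list[str]] = {}
    for term in graph.nodes:
        if graph.out_degree(term) == 0:
            parentless.setdefault(namespace_of[term], []).append(term)
    roots: dict[str, str] = {}
    for ns in {namespace_of[t] for t in graph.nodes}:
        candidates = sorted(parentless.get(ns, []))
        if len(candidates) != 1:
            raise OntologyError(
                f"namespace {ns} has {len(candidates)} parentless terms "
                f"({candidates}); expected exactly one root"
            )
        roots[ns] = candidates[0]
    return roots


def write_obo(onto: OntologyGraph, path: str, names: dict[str, str] | None = None) -> None:
    """Serialize an :class:`OntologyGraph` back to a minimal OBO 1.2 document."""
    names = names or {}
    lines = ["format-version: 1.2", ""]
    for term in sorted(onto.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {names.get(term, term)}")
        lines.append(f"namespace: {onto.namespace_of[term]}")
        for parent in sorted(onto.parents(term)):
            rel = onto.relation(term, parent)
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    with open(path, "w") as handle:
        handle.write("\n".join(lines))
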