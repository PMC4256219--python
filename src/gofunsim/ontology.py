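"""Ontology DAG structure and OBO parsing.

The Gene Ontology is a set of rooted directed acyclic graphs (one per
namespace: biological_process, molecular_function, cellular_component)
whose edges point from a child term to its parents via typed relations.
Only ``is_a`` and ``part_of`` edges participate in the similarity
measures implemented here; other relationship types (the regulates
family etc.) are counted and dropped at parse time.

Ancestor sets are *inclusive* of the query term throughout the package:
the commonality of a term with its own ancestor then contains that
ancestor, extended annotation sets are ancestor-closed supersets of the
direct sets, and every normalized similarity of a term with itself is 1.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: canonical short namespace codes keyed by OBO namespace names
NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

DEFAULT_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Structural problem in an ontology file (cycle, dangling parent...)."""


class UnknownTermError(KeyError):
    """Term id does not exist in the ontology."""


class ObsoleteTermError(KeyError):
    """Term id refers to an obsolete term."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    ``parents`` holds ``(parent_id, edge_type)`` tuples; obsolete terms
    carry no parents.
    """

    id: str
    name: str = ""
    namespace: str = "BP"
    parents: tuple[tuple[str, str], ...] = ()
    alt_ids: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass
class TermSet:
    """A set of term ids, all belonging to one namespace."""

    members: frozenset[str]
    namespace: str

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.members

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OntologyDAG:
    """Rooted DAG of terms for one namespace with typed child->parent edges."""

    namespace: str
    terms: dict[str, Term]
    root: str = ""
    children_index: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    obsolete_terms: dict[str, Term] = field(default_factory=dict)
    alt_id_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._finalize()

    def _finalize(self) -> None:
        self.children_index = {t: [] for t in self.terms}
        roots = []
        for term in self.terms.values():
            for parent, etype in term.parents:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.id} references undefined parent {parent}"
                    )
                self.children_index[parent].append((term.id, etype))
            if not term.parents:
                roots.append(term.id)
        self._check_acyclic()
        if len(roots) != 1:
            raise OntologyError(
                f"namespace {self.namespace} must have exactly one root, "
                f"found {sorted(roots)!r}"
            )
        self.root = roots[0]
        for aid, primary in list(self.alt_id_map.items()):
            if aid in self.terms:  # primary ids win over stray alt_ids
                del self.alt_id_map[aid]
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}
        self._topo: list[str] | None = None

    def _check_acyclic(self) -> None:
        graph = {t: [p for p, _ in term.parents] for t, term in self.terms.items()}
        try:
            list(TopologicalSorter(graph).static_order())
        except Exception as exc:  # graphlib.CycleError names the cycle
            cycle = getattr(exc, "args", (None, ()))[-1]
            member = cycle[0] if cycle else "?"
            raise OntologyError(f"cycle detected involving term {member}") from exc

    # -- lookups ---------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map a possibly-alternative id to its primary id.

        Raises :class:`ObsoleteTermError` for obsolete ids and
        :class:`UnknownTermError` for ids absent from the ontology, so
        callers can tell the two failure modes apart.
        """
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_id_map:
            return self.alt_id_map[term_id]
        if term_id in self.obsolete_terms:
            raise ObsoleteTermError(f"term {term_id} is obsolete")
        raise UnknownTermError(f"term {term_id} not found in {self.namespace} ontology")

    def parents(self, term_id: str) -> list[tuple[str, str]]:
        return list(self.terms[self.resolve(term_id)].parents)

    def children(self, term_id: str) -> list[tuple[str, str]]:
        return list(self.children_index[self.resolve(term_id)])

    def n_children(self, term_id: str) -> int:
        return len(self.children_index[self.resolve(term_id)])

    # -- traversal -------------------------------------------------------

    def ancestors(self, term_id: str, inclusive: bool = True) -> TermSet:
        """Transitive closure over parent edges of both types."""
        t = self.resolve(term_id)
        closure = self._ancestor_closure(t)
        members = closure if inclusive else closure - {t}
        return TermSet(frozenset(members), self.namespace)

    def descendants(self, term_id: str, inclusive: bool = True) -> TermSet:
        t = self.resolve(term_id)
        closure = self._descendant_closure(t)
        members = closure if inclusive else closure - {t}
        return TermSet(frozenset(members), self.namespace)

    def _ancestor_closure(self, t: str) -> frozenset[str]:
        cached = self._ancestor_cache.get(t)
        if cached is None:
            acc: set[str] = {t}
            for parent, _ in self.terms[t].parents:
                acc |= self._ancestor_closure(parent)
            cached = self._ancestor_cache[t] = frozenset(acc)
        return cached

    def _descendant_closure(self, t: str) -> frozenset[str]:
        cached = self._descendant_cache.get(t)
        if cached is None:
            acc: set[str] = {t}
            for child, _ in self.children_index[t]:
                acc |= self._descendant_closure(child)
            cached = self._descendant_cache[t] = frozenset(acc)
        return cached

    def topological_order(self) -> list[str]:
        """Terms ordered so that every parent precedes all its children."""
        if self._topo is None:
            graph = {
                t: [c for c, _ in children]
                for t, children in self.children_index.items()
            }
            self._topo = list(TopologicalSorter(graph).static_order())
            self._topo.reverse()  # sorter yields leaves-first for child lists
        return list(self._topo)

    def edge_count(self) -> int:
        return sum(len(t.parents) for t in self.terms.values())


def _namespace_code(raw: str | None) -> str:
    if raw is None:
        return "BP"
    return NAMESPACE_CODES.get(raw, raw)


def parse_obo(
    source,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> dict[str, OntologyDAG]:
    """Parse an OBO 1.2 flat file into one :class:`OntologyDAG` per namespace.

    Parameters
    ----------
    source
        Path, file object or OBO text.
    relations
        Relationship types loaded as edges; everything else is dropped
        with a logged count. ``is_a`` is always honoured.

    Returns
    -------
    dict mapping namespace code (``BP``/``MF``/``CC``) to its DAG.
    Obsolete terms are excluded from the graphs but kept for lookup;
    edges crossing namespaces are dropped with a warning.
    """
    relations = set(relations) | {"is_a"}
    if isinstance(source, str) and "[Term]" in source:
        source = io.StringIO(source)
    graph: nx.MultiDiGraph = obonet.read_obo(source, ignore_obsolete=False)

    node_ns = {
        n: _namespace_code(data.get("namespace"))
        for n, data in graph.nodes(data=True)
    }
    parents_by_term: dict[str, list[tuple[str, str]]] = {n: [] for n in graph}
    dropped_relations = 0
    cross_namespace = 0
    for child, parent, etype in graph.edges(keys=True):
        if etype not in relations:
            dropped_relations += 1
            continue
        if node_ns[child] != node_ns[parent]:
            cross_namespace += 1
            logger.warning(
                "dropping cross-namespace edge %s -> %s (%s)", child, parent, etype
            )
            continue
        parents_by_term[child].append((parent, etype))
    if dropped_relations:
        logger.info("ignored %d edges with unloaded relationship types", dropped_relations)

    by_ns: dict[str, dict[str, Term]] = {}
    obsolete_by_ns: dict[str, dict[str, Term]] = {}
    alt_by_ns: dict[str, dict[str, str]] = {}
    for node, data in graph.nodes(data=True):
        ns = node_ns[node]
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        term = Term(
            id=node,
            name=data.get("name", ""),
            namespace=ns,
            parents=() if obsolete else tuple(sorted(parents_by_term[node])),
            alt_ids=tuple(data.get("alt_id", ())),
            obsolete=obsolete,
        )
        if obsolete:
            obsolete_by_ns.setdefault(ns, {})[node] = term
            continue
        by_ns.setdefault(ns, {})[node] = term
        for aid in term.alt_ids:
            alt_by_ns.setdefault(ns, {})[aid] = node

    dags: dict[str, OntologyDAG] = {}
    for ns, terms in by_ns.items():
        dags[ns] = OntologyDAG(
            namespace=ns,
            terms=terms,
            obsolete_terms=obsolete_by_ns.get(ns, {}),
            alt_id_map=alt_by_ns.get(ns, {}),
        )
    return dags


def ontology_stats(dags: Mapping[str, OntologyDAG]) -> list[dict]:
    """Per-namespace term and edge counts (CLI ``ontology stats`` payload)."""
    rows = []
    for ns in sorted(dags):
        dag = dags[ns]
        rows.append(
            {
                "namespace": ns,
                "terms": len(dag),
                "edges": dag.edge_count(),
                "obsolete": len(dag.obsolete_terms),
                "root": dag.root,
            }
        )
    return rows
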