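"""Protein->GO annotation corpora: GAF parsing and true-path propagation.

A protein annotated to a term is implicitly annotated to every ancestor
of that term (the true-path rule).  The *extended* annotation set of a
protein is therefore the ancestor closure of its *direct* set, and a
term's corpus frequency counts the distinct proteins whose extended set
contains it — counting distinct proteins rather than annotation rows
removes duplicate-row bias.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .ontology import ObsoleteTermError, OntologyDAG, UnknownTermError

logger = logging.getLogger(__name__)

ASPECT_TO_NAMESPACE = {"P": "BP", "F": "MF", "C": "CC"}

GAF_COLUMNS = 17


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Annotations for one namespace.

    ``direct`` maps protein id to its directly annotated term set;
    ``evidence`` keeps the evidence codes seen for each (protein, term)
    pair so annotations can be filtered after parsing.  ``extended`` and
    ``term_protein_count`` are populated by :func:`propagate`.
    """

    namespace: str
    direct: dict[str, frozenset[str]]
    evidence: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    extended: dict[str, frozenset[str]] | None = None
    term_protein_count: dict[str, int] | None = None

    @property
    def corpus_size(self) -> int:
        return len(self.direct)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.direct)

    def __contains__(self, protein: str) -> bool:
        return protein in self.direct

    def direct_terms(self, protein: str) -> frozenset[str]:
        try:
            return self.direct[protein]
        except KeyError:
            raise AnnotationError(
                f"protein {protein} has no {self.namespace} annotation"
            ) from None

    def extended_terms(self, protein: str) -> frozenset[str]:
        if self.extended is None:
            raise AnnotationError("annotation set is not propagated; call propagate()")
        try:
            return self.extended[protein]
        except KeyError:
            raise AnnotationError(
                f"protein {protein} has no {self.namespace} annotation"
            ) from None


def parse_gaf(
    source,
    dags: Mapping[str, OntologyDAG],
    strict: bool = False,
) -> dict[str, AnnotationSet]:
    """Parse GAF 2.x text into one direct-only :class:`AnnotationSet` per namespace.

    Honoured columns: DB_Object_ID (2), Qualifier (4), GO_ID (5),
    Evidence (7), Aspect (9).  Rows whose qualifier contains ``NOT`` are
    dropped; GO ids are resolved through alt_id maps, and ids that are
    obsolete or unknown are dropped with a logged count (or raise in
    strict mode).  Duplicate rows collapse to one annotation whose
    evidence set is the union of the rows' codes.
    """
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        source = io.StringIO(source)
    elif isinstance(source, str):
        source = open(source)

    direct: dict[str, dict[str, set[str]]] = {ns: {} for ns in dags}
    evidence: dict[str, dict[tuple[str, str], set[str]]] = {ns: {} for ns in dags}
    n_dropped_terms = 0
    n_malformed = 0
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            if strict:
                raise AnnotationError(f"malformed GAF line {lineno}: {line!r}")
            n_malformed += 1
            logger.warning("skipping malformed GAF line %d", lineno)
            continue
        protein, qualifier, go_id, ev_code, aspect = (
            cols[1],
            cols[3],
            cols[4],
            cols[6],
            cols[8],
        )
        if "NOT" in qualifier.split("|"):
            continue
        ns = ASPECT_TO_NAMESPACE.get(aspect)
        if ns is None or ns not in dags:
            n_dropped_terms += 1
            continue
        try:
            term = dags[ns].resolve(go_id)
        except (UnknownTermError, ObsoleteTermError):
            n_dropped_terms += 1
            continue
        direct[ns].setdefault(protein, set()).add(term)
        evidence[ns].setdefault((protein, term), set()).add(ev_code)
    if n_dropped_terms:
        logger.info("dropped %d rows with unknown/obsolete terms or aspects", n_dropped_terms)

    return {
        ns: AnnotationSet(
            namespace=ns,
            direct={p: frozenset(ts) for p, ts in direct[ns].items()},
            evidence={k: frozenset(v) for k, v in evidence[ns].items()},
        )
        for ns in dags
    }


def filter_evidence(ann: AnnotationSet, exclude: Iterable[str]) -> AnnotationSet:
    """Remove annotations supported only by excluded evidence codes.

    Proteins left without annotations are dropped from the corpus.
    """
    exclude = frozenset(exclude)
    if not exclude:
        return AnnotationSet(ann.namespace, dict(ann.direct), dict(ann.evidence))
    direct: dict[str, frozenset[str]] = {}
    evidence: dict[tuple[str, str], frozenset[str]] = {}
    for protein, terms in ann.direct.items():
        kept = set()
        for term in terms:
            codes = ann.evidence.get((protein, term), frozenset())
            remaining = codes - exclude
            if remaining or not codes:
                kept.add(term)
                if codes:
                    evidence[(protein, term)] = remaining
        if kept:
            direct[protein] = frozenset(kept)
    return AnnotationSet(ann.namespace, direct, evidence)


def propagate(ann: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Apply the true-path rule: build extended sets and per-term counts.

    ``extended(p)`` is the union of inclusive ancestor sets of p's direct
    terms; ``term_protein_count(t)`` counts distinct proteins whose
    extended set contains t, so the root's count equals the corpus size.
    """
    extended: dict[str, frozenset[str]] = {}
    counts: dict[str, int] = {}
    for protein, terms in ann.direct.items():
        closure: set[str] = set()
        for t in terms:
            closure |= dag.ancestors(t, inclusive=True).members
        extended[protein] = frozenset(closure)
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    return AnnotationSet(
        namespace=ann.namespace,
        direct=dict(ann.direct),
        evidence=dict(ann.evidence),
        extended=extended,
        term_protein_count=counts,
    )


def annotation_stats(
    annsets: Mapping[str, AnnotationSet], top: int = 5
) -> list[dict]:
    """Per-namespace corpus sizes and top-frequency terms (CLI payload)."""
    rows = []
    for ns in sorted(annsets):
        ann = annsets[ns]
        counts = ann.term_protein_count or {}
        top_terms = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
        rows.append(
            {
                "namespace": ns,
                "proteins": ann.corpus_size,
                "annotations": sum(len(ts) for ts in ann.direct.values()),
                "top_terms": ";".join(f"{t}:{c}" for t, c in top_terms),
            }
        )
    return rows
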