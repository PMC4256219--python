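"""Term information-content models.

Four families of term specificity score are implemented, all in natural
log units:

* ``annotation`` — IC(t) = -ln of the relative corpus frequency of t,
  where frequency counts distinct proteins whose ancestor-closed
  annotation set contains t.  Corpus-dependent.
* ``zhang`` — IC(t) = -ln(D(t)/D(root)) where D(t) is the inclusive
  descendant count of t (a Seco-style, topology-only specificity).
* ``wang`` — the semantic value SV(t): each ancestor z of t contributes
  an S-value obtained by multiplying edge weights along the best path
  from t up to z (is_a 0.8, part_of 0.6 by default), and SV(t) is the
  sum over the inclusive ancestor set.  SV(t) >= 1, not 0 at the root.
* ``universal`` — a topological position characteristic rho with
  rho(root)=1 and rho(t) = max over parents q of rho(q)/|children(q)|;
  IC(t) = -ln rho(t).

Annotation IC is undefined for terms never seen in the corpus; querying
such a term raises rather than silently treating it as IC 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .annotation import AnnotationSet
from .ontology import OntologyDAG

DEFAULT_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class ICError(ValueError):
    pass


class TermNotInCorpusError(KeyError):
    """Annotation IC requested for a term absent from the corpus."""


@dataclass
class ICTable:
    """Map term -> information content for one model.

    For the Wang model ``svalues`` carries, per target term, the map
    {ancestor -> S-value} needed by the hybrid term-similarity formula.
    """

    model: str
    values: dict[str, float]
    svalues: dict[str, dict[str, float]] | None = None
    meta: dict = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.values

    def __getitem__(self, term: str) -> float:
        try:
            return self.values[term]
        except KeyError:
            if self.model == "annotation":
                raise TermNotInCorpusError(
                    f"term {term} not in annotation corpus"
                ) from None
            raise

    def __len__(self) -> int:
        return len(self.values)


def ic_annotation(ann: AnnotationSet, dag: OntologyDAG) -> ICTable:
    """Annotation-frequency IC from propagated protein counts."""
    counts = ann.term_protein_count
    if not counts:
        raise ICError("annotation IC needs a propagated, non-empty corpus")
    total = counts.get(dag.root, 0)
    if total <= 0:
        raise ICError("corpus has no annotated proteins under the root")
    values = {t: -math.log(c / total) or 0.0 for t, c in counts.items() if c > 0}
    return ICTable("annotation", values, meta={"corpus_size": total})


def descendant_counts(dag: OntologyDAG) -> dict[str, int]:
    """Inclusive descendant count D(t) for every term (Zhang D-value)."""
    return {t: len(dag.descendants(t, inclusive=True)) for t in dag.terms}


def ic_zhang(dag: OntologyDAG) -> ICTable:
    dvals = descendant_counts(dag)
    droot = dvals[dag.root]
    values = {t: -math.log(d / droot) or 0.0 for t, d in dvals.items()}
    return ICTable("zhang", values, meta={"d_root": droot})


def wang_svalues(
    dag: OntologyDAG,
    term: str,
    weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """S-value map {ancestor -> S} for one target term.

    S(term)=1; walking upward, an ancestor's S-value is the maximum over
    its children on a path to the target of (edge weight x child S).
    """
    w = dict(DEFAULT_WANG_WEIGHTS if weights is None else weights)
    t = dag.resolve(term)
    ancset = dag.ancestors(t, inclusive=True).members
    order = [u for u in dag.topological_order() if u in ancset]
    svals: dict[str, float] = {t: 1.0}
    for z in reversed(order):  # children before parents
        if z == t:
            continue
        best = 0.0
        for child, etype in dag.children_index[z]:
            if child in ancset and child in svals:
                cand = w.get(etype, 0.0) * svals[child]
                if cand > best:
                    best = cand
        svals[z] = best
    return svals


def ic_wang(
    dag: OntologyDAG, weights: Mapping[str, float] | None = None
) -> ICTable:
    """Semantic values SV(t) for every term, with per-term S-value maps."""
    w = dict(DEFAULT_WANG_WEIGHTS if weights is None else weights)
    svalues = {t: wang_svalues(dag, t, w) for t in dag.terms}
    values = {t: sum(sv.values()) for t, sv in svalues.items()}
    return ICTable("wang", values, svalues=svalues, meta={"weights": w})


def topological_weights(dag: OntologyDAG) -> dict[str, float]:
    """The rho characteristic: rho(root)=1, rho(t)=max_q rho(q)/|children(q)|."""
    rho: dict[str, float] = {}
    for t in dag.topological_order():
        if t == dag.root:
            rho[t] = 1.0
            continue
        rho[t] = max(
            rho[q] / len(dag.children_index[q]) for q, _ in dag.terms[t].parents
        )
    return rho


def ic_universal(dag: OntologyDAG) -> ICTable:
    rho = topological_weights(dag)
    values = {t: -math.log(r) or 0.0 for t, r in rho.items()}
    return ICTable("universal", values)


def compute_ic(
    model: str,
    dag: OntologyDAG,
    ann: AnnotationSet | None = None,
    wang_weights: Mapping[str, float] | None = None,
) -> ICTable:
    """Dispatch to one of the four IC models by name."""
    if model == "annotation":
        if ann is None:
            raise ICError("annotation IC requires an annotation corpus")
        return ic_annotation(ann, dag)
    if model == "zhang":
        return ic_zhang(dag)
    if model == "wang":
        return ic_wang(dag, wang_weights)
    if model == "universal":
        return ic_universal(dag)
    raise ICError(f"unknown IC model {model!r}; choose from "
                  "annotation, zhang, wang, universal")
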