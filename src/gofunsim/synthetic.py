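"""Synthetic ontologies, annotation corpora and benchmark instances.

Every generator is a pure function of its parameters and seed, and
everything it produces can be serialized to the standard flat formats
(OBO 1.2, GAF 2.2, TSV edge lists) and re-parsed losslessly, so the
whole pipeline is exercisable without any external download.

The generators emulate the salient statistics of real GO corpora:
rooted multi-parent DAGs mixing is_a and part_of edges, Zipf-skewed
term popularity (a few general terms annotate many proteins, most terms
few), true-path-consistent propagation, positive protein pairs that
share annotations (functional coherence of interacting proteins) and
planted-partition co-expression graphs whose communities are annotated
from disjoint regions of the ontology.

``fixture_F1`` is the package's frozen worked example: a six-term DAG
and five-protein corpus small enough that every IC value and similarity
score can be verified by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .annotation import AnnotationSet, parse_gaf, propagate
from .ontology import OntologyDAG, Term, parse_obo

NAMESPACE_NAMES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults describe a small but structured corpus: a 150-term DAG
    with occasional multiple parenthood and part_of edges, 200 proteins
    carrying 1 + Poisson(2) direct terms drawn with Zipf(1.0) skew, a
    fully separable positive-pair signal, and a 2-community planted
    co-expression graph at 0.9/0.05 edge densities.  The ontology is
    kept larger than the corpus so that, as in real GO corpora, most
    specific terms annotate only a handful of proteins.
    """

    n_terms: int = 150
    extra_parent_p: float = 0.3
    part_of_p: float = 0.2
    n_proteins: int = 200
    terms_per_protein_mean: float = 2.0
    zipf_alpha: float = 1.0
    signal: float = 1.0
    n_pairs: int = 100
    n_communities: int = 2
    community_size: int = 20
    p_within: float = 0.9
    p_between: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.extra_parent_p, self.part_of_p, self.signal,
                  self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise SyntheticError(f"probability {p} outside [0, 1]")
        if self.n_terms < 2:
            raise SyntheticError("need at least two terms (root + one)")


# -- the frozen worked fixture ------------------------------------------------

_F1_OBO = """\
format-version: 1.2
ontology: f1

[Term]
id: R
name: root
namespace: biological_process

[Term]
id: A
name: node A
namespace: biological_process
is_a: R

[Term]
id: B
name: node B
namespace: biological_process
is_a: R

[Term]
id: C
name: node C
namespace: biological_process
is_a: A
is_a: B

[Term]
id: D
name: node D
namespace: biological_process
relationship: part_of A

[Term]
id: E
name: node E
namespace: biological_process
is_a: A
is_a: B
"""

_F1_ANNOTATIONS = {"p1": "C", "p2": "D", "p3": "B", "p4": "A", "p5": "E"}


def fixture_F1() -> tuple[OntologyDAG, AnnotationSet]:
    """The canonical hand-checkable fixture: 6 terms, 5 proteins.

    Edges: A,B is_a R; C is_a A,B; D part_of A; E is_a A,B.
    Direct annotations: p1:C, p2:D, p3:B, p4:A, p5:E.  The returned
    annotation set is already propagated (counts R:5 A:4 B:3 C:1 D:1 E:1).
    """
    dag = parse_obo(_F1_OBO)["BP"]
    gaf = "\n".join(
        _gaf_line(protein, term, "BP") for protein, term in _F1_ANNOTATIONS.items()
    )
    ann = parse_gaf("!gaf-version: 2.2\n" + gaf + "\n", {"BP": dag})["BP"]
    return dag, propagate(ann, dag)


# -- serialization ------------------------------------------------------------


def dag_to_obo(dag: OntologyDAG) -> str:
    """Serialize a DAG to OBO 1.2 text that re-parses to the same DAG."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {term.name or tid}")
        lines.append(f"namespace: {NAMESPACE_NAMES.get(term.namespace, term.namespace)}")
        for parent, etype in sorted(term.parents):
            if etype == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {etype} {parent}")
        lines.append("")
    return "\n".join(lines)


_ASPECT = {"BP": "P", "MF": "F", "CC": "C"}


def _gaf_line(protein: str, term: str, ns: str, evidence: str = "IEA") -> str:
    cols = [
        "SYNT",          # DB
        protein,         # DB_Object_ID
        protein,         # DB_Object_Symbol
        "",              # Qualifier
        term,            # GO_ID
        "SYNT:0",        # DB:Reference
        evidence,        # Evidence
        "",              # With/From
        _ASPECT[ns],     # Aspect
        "",              # DB_Object_Name
        "",              # Synonym
        "protein",       # DB_Object_Type
        "taxon:9606",    # Taxon
        "20140415",      # Date
        "SYNT",          # Assigned_By
        "",              # Annotation_Extension
        "",              # Gene_Product_Form_ID
    ]
    return "\t".join(cols)


def annotations_to_gaf(ann: AnnotationSet) -> str:
    """Serialize direct annotations to GAF 2.2 text (round-trippable)."""
    lines = ["!gaf-version: 2.2"]
    for protein in sorted(ann.direct):
        for term in sorted(ann.direct[protein]):
            codes = ann.evidence.get((protein, term), frozenset({"IEA"}))
            for code in sorted(codes):
                lines.append(_gaf_line(protein, term, ann.namespace, code))
    return "\n".join(lines) + "\n"


# -- random generators --------------------------------------------------------


def random_dag(spec: SyntheticSpec, seed: int | None = None) -> OntologyDAG:
    """Random rooted DAG: term i > 0 takes one uniform parent among the
    earlier terms, plus one extra distinct parent with probability
    ``extra_parent_p``; edge types are part_of with probability
    ``part_of_p``.  Acyclic by construction (parents precede children)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids = [f"T{i:04d}" for i in range(spec.n_terms)]
    terms: dict[str, Term] = {}
    terms[ids[0]] = Term(id=ids[0], name="root", namespace="BP")
    for i in range(1, spec.n_terms):
        parents = {int(rng.integers(0, i))}
        if i > 1 and rng.random() < spec.extra_parent_p:
            extra = int(rng.integers(0, i))
            while extra in parents:
                extra = int(rng.integers(0, i))
            parents.add(extra)
        typed = tuple(
            sorted(
                (ids[p], "part_of" if rng.random() < spec.part_of_p else "is_a")
                for p in parents
            )
        )
        terms[ids[i]] = Term(id=ids[i], name=f"term {i}", namespace="BP", parents=typed)
    return OntologyDAG(namespace="BP", terms=terms)


def _zipf_weights(n: int, alpha: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-alpha)
    return w / w.sum()


def random_annotations(
    dag: OntologyDAG, spec: SyntheticSpec, seed: int | None = None
) -> tuple[AnnotationSet, str]:
    """Zipf-skewed corpus over the non-root terms, plus its GAF text.

    Each protein draws k = 1 + Poisson(mean) distinct direct terms with
    popularity proportional to rank^-alpha over term creation order
    (alpha=0 is uniform).  Returns the propagated annotation set and
    GAF 2.2 text that re-parses to the same direct sets.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    pool = [t for t in dag.topological_order() if t != dag.root]
    if not pool:
        raise SyntheticError("ontology has no non-root terms to annotate with")
    weights = _zipf_weights(len(pool), spec.zipf_alpha)
    direct: dict[str, frozenset[str]] = {}
    for i in range(spec.n_proteins):
        k = 1 + int(rng.poisson(spec.terms_per_protein_mean))
        k = min(k, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False, p=weights)
        direct[f"P{i:04d}"] = frozenset(pool[j] for j in idx)
    ann = AnnotationSet(namespace=dag.namespace, direct=direct)
    ann = propagate(ann, dag)
    return ann, annotations_to_gaf(ann)


def planted_ppi(
    dag: OntologyDAG,
    ann: AnnotationSet,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Positive/negative protein-pair sets with a tunable coherence signal.

    With probability ``signal`` a positive pair is a functionally
    coherent pair — drawn from the pairs sharing at least one direct
    term, ranked by coherence, most coherent first — otherwise it is a
    uniform random pair.  Coherence is the total specificity of the
    shared terms (sum of 1/popularity) scaled by the shared fraction of
    the pair's direct annotation, 2|shared| / (|A| + |B|): interacting
    proteins share *specific* functions and share *most* of what they
    do, which is the structure real interaction sets show.  The signal
    is mechanistic (shared direct terms), not any of the evaluated
    similarity measures.  Negatives are uniform random distinct
    non-positive pairs, in equal number.
    """
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    proteins = ann.proteins
    if len(proteins) < 4:
        raise SyntheticError("corpus too small to plant protein pairs")
    popularity: dict[str, int] = {}
    for p in proteins:
        for t in ann.direct[p]:
            popularity[t] = popularity.get(t, 0) + 1
    candidates: list[tuple[str, str]] = []
    coherence: list[float] = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            shared = ann.direct[a] & ann.direct[b]
            if shared:
                candidates.append((a, b))
                specificity = sum(1.0 / popularity[t] for t in shared)
                fraction = 2 * len(shared) / (
                    len(ann.direct[a]) + len(ann.direct[b])
                )
                coherence.append(specificity * fraction)
    if not candidates:
        raise SyntheticError("no protein pair shares a term; cannot plant signal")
    order = sorted(
        range(len(candidates)),
        key=lambda k: (-coherence[k], rng.random()),
    )
    ranked = iter(order)

    positives: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    attempts = 0
    while len(positives) < spec.n_pairs:
        attempts += 1
        if attempts > 100 * spec.n_pairs:
            raise SyntheticError("could not plant enough distinct positive pairs")
        if rng.random() < spec.signal:
            try:
                a, b = candidates[next(ranked)]
            except StopIteration:
                raise SyntheticError(
                    "fewer coherent pairs than requested positives"
                ) from None
        else:
            i, j = rng.choice(len(proteins), size=2, replace=False)
            a, b = proteins[i], proteins[j]
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        positives.append((a, b) if a < b else (b, a))

    negatives: list[tuple[str, str]] = []
    while len(negatives) < len(positives):
        i, j = rng.choice(len(proteins), size=2, replace=False)
        a, b = proteins[i], proteins[j]
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        negatives.append((a, b) if a < b else (b, a))
    return positives, negatives


def planted_coexpression(
    dag: OntologyDAG,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> tuple[list[tuple[str, str, float]], dict[str, int], AnnotationSet]:
    """Planted-partition co-expression graph with community-specific
    annotations.

    Nodes split into ``n_communities`` blocks of ``community_size``;
    within-block edges appear with probability ``p_within`` (weights
    U(0.7, 1.0)), between-block with ``p_between`` (weights U(0.1, 0.4)).
    Each community annotates its proteins from a distinct block of the
    ontology's non-root terms, so communities share no direct terms.
    Returns (weighted edges, true labels, propagated annotations).
    """
    if spec.n_communities < 2:
        raise SyntheticError("need at least two communities")
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    pool = [t for t in dag.topological_order() if t != dag.root]
    block_size = len(pool) // spec.n_communities
    if block_size < 1:
        raise SyntheticError("ontology too small for the requested communities")
    blocks = [
        pool[c * block_size : (c + 1) * block_size]
        for c in range(spec.n_communities)
    ]

    labels: dict[str, int] = {}
    direct: dict[str, frozenset[str]] = {}
    nodes: list[str] = []
    for c, block in enumerate(blocks):
        weights = _zipf_weights(len(block), spec.zipf_alpha)
        for i in range(spec.community_size):
            name = f"C{c}_{i:03d}"
            nodes.append(name)
            labels[name] = c
            k = min(1 + int(rng.poisson(spec.terms_per_protein_mean)), len(block))
            idx = rng.choice(len(block), size=k, replace=False, p=weights)
            direct[name] = frozenset(block[j] for j in idx)

    edges: list[tuple[str, str, float]] = []
    for a, b in _all_pairs(nodes):
        same = labels[a] == labels[b]
        p = spec.p_within if same else spec.p_between
        if rng.random() < p:
            lo, hi = (0.7, 1.0) if same else (0.1, 0.4)
            edges.append((a, b, float(rng.uniform(lo, hi))))

    ann = propagate(AnnotationSet(namespace=dag.namespace, direct=direct), dag)
    return edges, labels, ann


def _all_pairs(items: Sequence[str]):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
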