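"""Evaluation protocols for functional similarity measures.

Three protocols mirror how similarity measures are benchmarked in
practice:

* correlation of measure scores with a reference similarity vector
  (sequence, Pfam-domain or EC similarity) via Pearson's r;
* functional-coherence classification of protein-protein interactions:
  score a positive (interacting) pair set and an equal-size random
  negative set and summarize the separation by the area under the ROC
  curve — a realistic classifier must exceed AUC 0.5;
* clustering power on a weighted co-expression graph: partition the
  graph by Louvain modularity maximization to obtain a ground truth,
  re-weight edges with the measure's similarity scores, re-cluster and
  compare the partitions by entropy-based normalized mutual information
  and the Rand index of pairwise cluster memberships.

Entropies and mutual information use natural logarithms.  The NMI
denominator defaults to (H_g + H_c)/2 (i.e. NMI = 2I/(H_g+H_c)); the
geometric-mean variant sqrt(H_g x H_c) is available via ``variant``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities
from scipy import stats
from sklearn.metrics import roc_curve

from .annotation import AnnotationSet
from .funcsim import MeasureConfig, SimilarityEngine
from .ontology import OntologyDAG

Pair = tuple[str, str]


class EvaluationError(ValueError):
    pass


# -- negative sampling and ROC ------------------------------------------------


def sample_negatives(
    proteins: Sequence[str],
    n: int,
    forbidden: Iterable[Pair] = (),
    seed: int | None = None,
) -> list[Pair]:
    """Sample n distinct unordered protein pairs uniformly at random,
    excluding self-pairs and any pair in ``forbidden``."""
    rng = np.random.default_rng(seed)
    proteins = sorted(set(proteins))
    forbidden_set = {frozenset(p) for p in forbidden}
    k = len(proteins)
    available = k * (k - 1) // 2 - sum(
        1
        for f in forbidden_set
        if len(f) == 2 and f <= set(proteins)
    )
    if n > available:
        raise EvaluationError(
            f"requested {n} negative pairs but only {available} are available"
        )
    chosen: set[frozenset] = set()
    out: list[Pair] = []
    while len(out) < n:
        i, j = rng.choice(k, size=2, replace=False)
        a, b = proteins[i], proteins[j]
        key = frozenset((a, b))
        if key in forbidden_set or key in chosen:
            continue
        chosen.add(key)
        out.append((a, b) if a < b else (b, a))
    return out


def roc_auc(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, pd.DataFrame]:
    """Rank-statistic AUC plus the ROC curve at every distinct threshold.

    The AUC is the fraction of (positive, negative) score pairs ordered
    correctly, counting ties as 1/2 — computed from midranks, so it is
    exact and threshold-free.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both positive and negative score sets are required")
    if np.isnan(pos).any() or np.isnan(neg).any():
        raise EvaluationError("NaN similarity scores cannot be ranked")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size
    )
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, thresholds = roc_curve(labels, np.concatenate([pos, neg]))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(auc), points


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation between two score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise EvaluationError("score vectors must share a length of at least 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EvaluationError("Pearson correlation undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


# -- clustering and partition comparison --------------------------------------


def cluster_graph(
    edges: Iterable[tuple[str, str, float]],
    seed: int | None = None,
    nodes: Iterable[str] = (),
    resolution: float = 1.0,
) -> dict[str, int]:
    """Louvain modularity partition of a weighted graph.

    Deterministic under a fixed seed; isolated nodes (listed in
    ``nodes`` but touched by no edge) become singleton clusters.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, *w in edges:
        weight = float(w[0]) if w else 1.0
        if weight < 0:
            raise EvaluationError(f"negative edge weight on ({a}, {b})")
        g.add_edge(a, b, weight=weight)
    if g.number_of_nodes() == 0:
        raise EvaluationError("cannot cluster an empty graph")
    communities = louvain_communities(g, weight="weight", seed=seed,
                                      resolution=resolution)
    # stable cluster ids: order communities by their smallest member
    communities = sorted(communities, key=lambda c: min(c))
    return {node: idx for idx, comm in enumerate(communities) for node in comm}


@dataclass
class PartitionComparison:
    """Agreement statistics between a ground-truth partition and a
    clustering of the same protein universe."""

    n: int
    contingency: pd.DataFrame
    entropy_truth: float
    entropy_clustering: float
    mutual_information: float
    nmi: float
    rand_index: float
    variant: str = "sum"
    sizes_truth: dict = field(default_factory=dict)
    sizes_clustering: dict = field(default_factory=dict)


def _entropy(sizes: Sequence[int], n: int) -> float:
    return -sum((s / n) * math.log(s / n) for s in sizes if s > 0)


def compare_partitions(
    truth: Mapping[str, int],
    clustering: Mapping[str, int],
    variant: str = "sum",
) -> PartitionComparison:
    """Entropy, mutual information, NMI and Rand index of two partitions.

    NMI = 2I/(H_g+H_c) (``variant="sum"``) or I/sqrt(H_g*H_c)
    (``variant="sqrt"``); it is defined as 1 when both entropies vanish.
    The Rand index counts pairs co-clustered in both partitions plus
    pairs separated in both, over all protein pairs.
    """
    if set(truth) != set(clustering):
        raise EvaluationError("partitions must cover the same protein universe")
    n = len(truth)
    if n < 2:
        raise EvaluationError("need at least two proteins to compare partitions")
    g_labels = sorted(set(truth.values()))
    c_labels = sorted(set(clustering.values()))
    table = pd.DataFrame(0, index=g_labels, columns=c_labels, dtype=int)
    for p in truth:
        table.loc[truth[p], clustering[p]] += 1
    ni = table.sum(axis=1)
    nj = table.sum(axis=0)
    h_g = _entropy(ni.tolist(), n)
    h_c = _entropy(nj.tolist(), n)
    mi = 0.0
    for i in g_labels:
        for j in c_labels:
            nij = table.loc[i, j]
            if nij > 0:
                mi += (nij / n) * math.log(n * nij / (ni[i] * nj[j]))
    if h_g == 0.0 and h_c == 0.0:
        nmi = 1.0
    elif variant == "sum":
        nmi = 2.0 * mi / (h_g + h_c)
    elif variant == "sqrt":
        nmi = mi / math.sqrt(h_g * h_c) if h_g > 0 and h_c > 0 else 0.0
    else:
        raise EvaluationError(f"unknown NMI variant {variant!r}")

    # Rand index from the contingency table pair counts
    comb2 = lambda v: v * (v - 1) // 2
    sum_ij = int(sum(comb2(int(v)) for v in table.to_numpy().ravel()))
    sum_i = int(sum(comb2(int(v)) for v in ni))
    sum_j = int(sum(comb2(int(v)) for v in nj))
    total = comb2(n)
    a = sum_ij
    b = total - sum_i - sum_j + sum_ij
    rand = (a + b) / total

    return PartitionComparison(
        n=n,
        contingency=table,
        entropy_truth=h_g,
        entropy_clustering=h_c,
        mutual_information=mi,
        nmi=min(1.0, max(0.0, nmi)),
        rand_index=rand,
        variant=variant,
        sizes_truth=ni.to_dict(),
        sizes_clustering=nj.to_dict(),
    )


# -- end-to-end protocols -----------------------------------------------------


def eval_ppi(
    positives: Sequence[Pair],
    ann: AnnotationSet,
    dag: OntologyDAG,
    configs: Sequence[MeasureConfig],
    seed: int | None = None,
    negatives: Sequence[Pair] | None = None,
    engine: SimilarityEngine | None = None,
) -> pd.DataFrame:
    """AUC of each measure at separating interacting pairs from random pairs.

    Negatives default to an equal-size uniform sample of annotated
    protein pairs excluding the positives.
    """
    if engine is None:
        engine = SimilarityEngine(dag, ann)
    positives = [p for p in positives if p[0] in ann and p[1] in ann]
    if not positives:
        raise EvaluationError("no positive pair has both proteins annotated")
    if negatives is None:
        negatives = sample_negatives(
            ann.proteins, len(positives), forbidden=positives, seed=seed
        )
    rows = []
    for config in configs:
        pos_scores = [engine.score(a, b, config) for a, b in positives]
        neg_scores = [engine.score(a, b, config) for a, b in negatives]
        auc, _ = roc_auc(pos_scores, neg_scores)
        rows.append({"measure": config.label, "auc": auc})
    return pd.DataFrame(rows)


def eval_clustering(
    edges: Sequence[tuple[str, str, float]],
    ann: AnnotationSet,
    dag: OntologyDAG,
    configs: Sequence[MeasureConfig],
    seed: int | None = None,
    engine: SimilarityEngine | None = None,
    nmi_variant: str = "sum",
) -> pd.DataFrame:
    """Clustering power of each measure on a weighted co-expression graph.

    The Louvain partition of the original weights is the ground truth;
    for each measure the edges are re-weighted by functional similarity,
    re-clustered with the same seed, and compared by NMI and Rand index.
    """
    if engine is None:
        engine = SimilarityEngine(dag, ann)
    truth = cluster_graph(edges, seed=seed)
    rows = []
    for config in configs:
        reweighted = [(a, b, engine.score(a, b, config)) for a, b, *_ in edges]
        part = cluster_graph(reweighted, seed=seed, nodes=truth)
        cmp = compare_partitions(truth, part, variant=nmi_variant)
        rows.append(
            {"measure": config.label, "nmi": cmp.nmi, "rand_index": cmp.rand_index}
        )
    return pd.DataFrame(rows)
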