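"""Protein-level functional similarity measures and the measure grid.

Two classes of measure map a pair of annotated proteins to a score:

* pairwise-term measures build the m x n matrix of term similarities
  between the proteins' *direct* annotation sets and aggregate it —
  ``avg`` (grand mean), ``max`` (grand maximum), ``abm`` (mean of all
  row and column best matches) and ``bma`` (mean of the two directional
  best-match averages);
* direct-IC set measures compare the *extended* (ancestor-closed)
  annotation sets through IC-weighted overlap indices — ``simgic``
  (Jaccard), ``simdic`` (Dice/Czekanowski), ``simuic`` (max-normalized
  universal) — plus ``simui``, the unweighted Jaccard, which equals
  SimGIC under an IC table assigning 1 to every term.

Crossing IC/term-similarity approaches with these measures yields the
57-configuration grid enumerated by :func:`enumerate_measures`:
8 annotation-based term models x 4 strategies, 3 topology approaches x
4 strategies, 4 IC families x 3 weighted set measures, and SimUI.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .ic import ICTable, compute_ic
from .ontology import OntologyDAG
from .termsim import term_sim

logger = logging.getLogger(__name__)

PAIRWISE_STRATEGIES = ("avg", "max", "abm", "bma")
DIRECT_MEASURES = ("simgic", "simdic", "simuic", "simui")

#: label prefixes per term-similarity approach (annotation family)
_ANNOTATION_MODELS = (
    ("resnik", False, "R"),
    ("resnik", True, "XR"),
    ("nunivers", False, "N"),
    ("nunivers", True, "XN"),
    ("lin", False, "L"),
    ("lin", True, "XL"),
    ("li", False, "Li"),
    ("relevance", False, "S"),
)

#: topology approaches: family -> (label prefix, default term-sim model)
_TOPOLOGY_MODELS = {
    "zhang": ("Z", "resnik"),
    "wang": ("W", "wang"),
    "universal": ("U", "nunivers"),
}

_FAMILY_PREFIX = {"annotation": "A", "zhang": "Z", "wang": "W", "universal": "U"}
_DIRECT_SUFFIX = {"simgic": "GIC", "simdic": "DIC", "simuic": "UIC"}
_STRATEGY_SUFFIX = {"avg": "Avg", "max": "Max", "abm": "ABM", "bma": "BMA"}


class FuncSimError(ValueError):
    pass


@dataclass(frozen=True)
class MeasureConfig:
    """One cell of the measure grid.

    Pairwise configs carry a term-similarity model (and possibly the
    XGraSM flag); direct-IC configs carry only the IC family.  SimUI
    carries neither.
    """

    label: str
    functional: str
    family: str | None = None
    termsim_model: str | None = None
    xgrasm: bool = False

    @property
    def is_pairwise(self) -> bool:
        return self.functional in PAIRWISE_STRATEGIES

    @property
    def normalized(self) -> bool:
        """Whether scores are guaranteed to lie in [0, 1]."""
        if not self.is_pairwise:
            return True
        return self.termsim_model != "resnik"

    @property
    def self_identity(self) -> bool:
        """Whether sim(p, p) = 1 holds by construction.

        True for all direct-IC set measures, and for best-match style
        aggregations (max/abm/bma) of term models whose self-similarity
        is exactly 1 (lin, nunivers, wang without corrections).  Avg
        mixes non-identical term pairs, and the Relevance/Li/XGraSM
        corrections stay strictly below 1 even on a self-pair, so those
        configurations score self-pairs below 1 by design.
        """
        if not self.is_pairwise:
            return True
        return (
            self.functional in ("max", "abm", "bma")
            and self.termsim_model in ("lin", "nunivers", "wang")
            and not self.xgrasm
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


def enumerate_measures() -> list[MeasureConfig]:
    """The full grid of 57 labeled measure configurations."""
    configs: list[MeasureConfig] = []
    for (model, xgrasm, prefix), strategy in itertools.product(
        _ANNOTATION_MODELS, PAIRWISE_STRATEGIES
    ):
        configs.append(
            MeasureConfig(
                label=prefix + _STRATEGY_SUFFIX[strategy],
                functional=strategy,
                family="annotation",
                termsim_model=model,
                xgrasm=xgrasm,
            )
        )
    for family, (prefix, model) in _TOPOLOGY_MODELS.items():
        for strategy in PAIRWISE_STRATEGIES:
            configs.append(
                MeasureConfig(
                    label=prefix + _STRATEGY_SUFFIX[strategy],
                    functional=strategy,
                    family=family,
                    termsim_model=model,
                )
            )
    for family, measure in itertools.product(
        _FAMILY_PREFIX, ("simgic", "simdic", "simuic")
    ):
        configs.append(
            MeasureConfig(
                label=_FAMILY_PREFIX[family] + _DIRECT_SUFFIX[measure],
                functional=measure,
                family=family,
            )
        )
    configs.append(MeasureConfig(label="SimUI", functional="simui"))
    return configs


def measure_by_label(label: str) -> MeasureConfig:
    for config in enumerate_measures():
        if config.label == label:
            return config
    valid = ", ".join(c.label for c in enumerate_measures())
    raise FuncSimError(f"unknown measure label {label!r}; valid labels: {valid}")


# -- aggregation of term-similarity matrices ---------------------------------


def pairwise_funcsim(simmatrix, strategy: str) -> float:
    """Aggregate an m x n matrix of term similarities into one score."""
    m = np.asarray(simmatrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise FuncSimError("similarity matrix must be non-empty and 2-D")
    if strategy == "avg":
        return float(m.mean())
    if strategy == "max":
        return float(m.max())
    row_best = m.max(axis=1)
    col_best = m.max(axis=0)
    if strategy == "abm":
        return float((row_best.sum() + col_best.sum()) / (m.shape[0] + m.shape[1]))
    if strategy == "bma":
        return float(0.5 * (row_best.mean() + col_best.mean()))
    raise FuncSimError(f"unknown pairwise strategy {strategy!r}")


# -- direct-IC set measures ---------------------------------------------------


def direct_funcsim(
    ext_a: frozenset[str],
    ext_b: frozenset[str],
    ic: ICTable | None,
    measure: str,
) -> float:
    """IC-weighted overlap of two ancestor-closed term sets."""
    if not ext_a or not ext_b:
        raise FuncSimError("extended annotation sets must be non-empty")
    if measure == "simui":
        inter = len(ext_a & ext_b)
        union = len(ext_a | ext_b)
        return inter / union
    if ic is None:
        raise FuncSimError(f"measure {measure} requires an IC table")
    i = sum(ic[t] for t in ext_a & ext_b)
    sa = sum(ic[t] for t in ext_a)
    sb = sum(ic[t] for t in ext_b)
    if measure == "simgic":
        u = sum(ic[t] for t in ext_a | ext_b)
        return _safe_ratio(i, u)
    if measure == "simdic":
        return _safe_ratio(2.0 * i, sa + sb)
    if measure == "simuic":
        return _safe_ratio(i, max(sa, sb))
    raise FuncSimError(f"unknown direct measure {measure!r}")


def _safe_ratio(num: float, den: float) -> float:
    if den == 0.0:
        logger.warning("all-zero IC denominator; similarity defined as 0")
        return 0.0
    return num / den


# -- full protein-pair scoring ------------------------------------------------


def funcsim(
    ann: AnnotationSet,
    protein_a: str,
    protein_b: str,
    config: MeasureConfig,
    dag: OntologyDAG,
    ic: ICTable | None = None,
    termset: str = "direct",
) -> float:
    """Score one protein pair under one measure configuration.

    Pairwise configs score the term-similarity matrix over the
    proteins' direct sets (or extended sets with ``termset="extended"``);
    direct-IC configs always use the extended sets.  Proteins without
    annotations raise rather than scoring 0.
    """
    if config.is_pairwise:
        if ic is None:
            raise FuncSimError(f"measure {config.label} requires an IC table")
        getter = (
            ann.extended_terms if termset == "extended" else ann.direct_terms
        )
        terms_a = sorted(getter(protein_a))
        terms_b = sorted(getter(protein_b))
        matrix = [
            [
                term_sim(dag, ic, ta, tb, config.termsim_model, config.xgrasm)
                for tb in terms_b
            ]
            for ta in terms_a
        ]
        return pairwise_funcsim(matrix, config.functional)
    ext_a = ann.extended_terms(protein_a)
    ext_b = ann.extended_terms(protein_b)
    return direct_funcsim(ext_a, ext_b, ic, config.functional)


class SimilarityEngine:
    """Scores protein pairs under any grid configuration, caching the
    per-family IC tables for one (ontology, corpus) pair."""

    def __init__(
        self,
        dag: OntologyDAG,
        ann: AnnotationSet,
        wang_weights: Mapping[str, float] | None = None,
        termset: str = "direct",
    ):
        if ann.extended is None:
            raise FuncSimError("annotation set must be propagated")
        self.dag = dag
        self.ann = ann
        self.wang_weights = wang_weights
        self.termset = termset
        self._tables: dict[str, ICTable] = {}

    def ic_table(self, family: str | None) -> ICTable | None:
        if family is None:
            return None
        if family not in self._tables:
            self._tables[family] = compute_ic(
                family, self.dag, ann=self.ann, wang_weights=self.wang_weights
            )
        return self._tables[family]

    def score(self, protein_a: str, protein_b: str, config: MeasureConfig) -> float:
        return funcsim(
            self.ann,
            protein_a,
            protein_b,
            config,
            self.dag,
            ic=self.ic_table(config.family),
            termset=self.termset,
        )

    def score_pairs(
        self,
        pairs: Sequence[tuple[str, str]],
        configs: Sequence[MeasureConfig],
    ) -> pd.DataFrame:
        """Long-form table: one row per pair, one column per measure label."""
        data = {"protein_a": [a for a, _ in pairs], "protein_b": [b for _, b in pairs]}
        for config in configs:
            data[config.label] = [self.score(a, b, config) for a, b in pairs]
        return pd.DataFrame(data)


def similarity_matrix(
    proteins: Sequence[str],
    config: MeasureConfig,
    dag: OntologyDAG,
    ann: AnnotationSet,
    ic: ICTable | None = None,
    wang_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Symmetric all-vs-all similarity matrix for a protein list."""
    engine = SimilarityEngine(dag, ann, wang_weights=wang_weights)
    if ic is not None:
        engine._tables[config.family] = ic
    n = len(proteins)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = engine.score(proteins[i], proteins[j], config)
            out[i, j] = out[j, i] = s
    return pd.DataFrame(out, index=list(proteins), columns=list(proteins))
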