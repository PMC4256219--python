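"""Term-level semantic similarity models.

All node-based models share one skeleton: a commonality score S for the
pair — the IC of the most informative common ancestor (MICA), or, with
the XGraSM enhancement, the mean IC over *all* informative (IC > 0)
common ancestors — normalized against the ICs of the two terms:

* ``resnik``     sim = S                      (unnormalized)
* ``lin``        sim = 2S / (IC(t1)+IC(t2))
* ``nunivers``   sim = S / max(IC(t1), IC(t2))
* ``relevance``  sim = lin x (1 - e^{-S})     (Schlicker correction;
  under annotation IC, 1 - e^{-S} is exactly 1 - p(MICA))
* ``li``         sim = lin x (1 - 1/(1+S))    (information coefficient)
* ``wang``       hybrid S-value formula, requiring a Wang ICTable:
  sim = sum over common ancestors of (S_t1(z)+S_t2(z)) / (SV(t1)+SV(t2))

Relevance and Li were proposed for annotation IC; applying them to a
topology table is permitted but flagged in the returned metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

from .ic import ICTable
from .ontology import OntologyDAG, TermSet

PAIRWISE_MODELS = ("resnik", "lin", "nunivers", "relevance", "li", "wang")

import math


class TermSimError(ValueError):
    pass


@dataclass
class TermPairContext:
    """Shared-ancestor context for one term pair under one IC table."""

    t1: str
    t2: str
    common_ancestors: TermSet
    mica: str
    informative_commons: frozenset[str]

    @property
    def n_informative(self) -> int:
        return len(self.informative_commons)


def pair_context(
    dag: OntologyDAG, ic: ICTable, t1: str, t2: str
) -> TermPairContext:
    """Common (inclusive) ancestors, the MICA and the informative subset.

    MICA ties are broken by the lexicographically smallest term id so
    results are reproducible.
    """
    a, b = dag.resolve(t1), dag.resolve(t2)
    common = dag.ancestors(a, inclusive=True).members & dag.ancestors(
        b, inclusive=True
    ).members
    if not common:
        raise TermSimError(f"terms {t1} and {t2} share no ancestors")
    mica = min(common, key=lambda t: (-ic[t], t))
    informative = frozenset(t for t in common if ic[t] > 0)
    return TermPairContext(
        t1=a,
        t2=b,
        common_ancestors=TermSet(frozenset(common), dag.namespace),
        mica=mica,
        informative_commons=informative,
    )


def _commonality(ctx: TermPairContext, ic: ICTable, xgrasm: bool) -> float:
    if not xgrasm:
        return ic[ctx.mica]
    if not ctx.informative_commons:
        return 0.0
    return fmean(ic[t] for t in ctx.informative_commons)


def term_sim(
    dag: OntologyDAG,
    ic: ICTable,
    t1: str,
    t2: str,
    model: str = "resnik",
    xgrasm: bool = False,
) -> float:
    """Semantic similarity of two same-namespace terms under one model."""
    if model not in PAIRWISE_MODELS:
        raise TermSimError(
            f"unknown term-similarity model {model!r}; choose from {PAIRWISE_MODELS}"
        )
    if model == "wang":
        if xgrasm:
            raise TermSimError("XGraSM is not defined for the Wang hybrid formula")
        return _wang_sim(dag, ic, t1, t2)

    ctx = pair_context(dag, ic, t1, t2)
    s = _commonality(ctx, ic, xgrasm)
    ic1, ic2 = ic[ctx.t1], ic[ctx.t2]

    if model == "resnik":
        return s
    if ic1 == 0.0 and ic2 == 0.0:
        # both terms carry no information; normalized similarity is 0
        return 0.0
    lin = 2.0 * s / (ic1 + ic2)
    if model == "lin":
        return lin
    if model == "nunivers":
        return s / max(ic1, ic2)
    if model == "relevance":
        return lin * (1.0 - math.exp(-s))
    if model == "li":
        return lin * (1.0 - 1.0 / (1.0 + s))
    raise AssertionError(model)


def _wang_sim(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> float:
    if ic.model != "wang" or ic.svalues is None:
        raise TermSimError("wang term similarity requires a Wang ICTable with S-values")
    a, b = dag.resolve(t1), dag.resolve(t2)
    sa, sb = ic.svalues[a], ic.svalues[b]
    common = sa.keys() & sb.keys()
    if not common:
        raise TermSimError(f"terms {t1} and {t2} share no ancestors")
    num = sum(sa[z] + sb[z] for z in common)
    return num / (ic[a] + ic[b])
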