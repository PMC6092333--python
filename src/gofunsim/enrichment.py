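"""Query-conditional enrichment of term information content.

A term's corpus- or structure-based IC ignores how the term is
represented in the querying gene pair or set.  Here the probability of a
term is augmented by the hypergeometric probability of its observed
annotation multiplicity: if ``k`` of the ``n`` query genes are annotated
by a term that annotates ``M`` of the ``N`` corpus genes,

    p*(t) = p(k, n | t) * p(t),   p(k, n | t) ~ Hypergeometric(N, M, n)

so the enriched IC is ``IC*(t) = -log p(k, n | t) + IC(t) >= IC(t)``.
Substituting IC* for IC in any functional-similarity measure yields its
enriched (starred) variant.  For a gene pair (n = 2) the correction has
closed forms for partial (k = 1) and complete (k = 2) annotation.

Binomial coefficients are evaluated with exact integer arithmetic
(``math.comb``), so the pmf is correct to float rounding at any corpus
size reached in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotations import AnnotationCorpus
from .exceptions import InconsistentContextError, UnknownGeneError
from .ic import ICTable

__all__ = [
    "QueryContext",
    "build_context",
    "hypergeom_pmf",
    "enriched_ic",
    "enriched_ic_pair_partial",
    "enriched_ic_pair_full",
    "enriched_ic_table",
    "classify_pair_terms",
]


@dataclass
class QueryContext:
    """Per-term annotation multiplicity within a query of n genes.

    ``k[t]`` counts the query genes whose propagated term set contains
    ``t``; terms with k = 0 are omitted.
    """

    genes: tuple[str, ...]
    n: int
    k: dict[str, int]

    @classmethod
    def from_term_sets(cls, term_sets: Sequence[Iterable[str]],
                       genes: tuple[str, ...] = ()) -> "QueryContext":
        k: dict[str, int] = {}
        for terms in term_sets:
            for t in set(terms):
                k[t] = k.get(t, 0) + 1
        return cls(genes=genes or tuple(f"set{i}" for i in range(len(term_sets))),
                   n=len(term_sets), k=k)


def build_context(corpus: AnnotationCorpus, genes: Sequence[str]) -> QueryContext:
    """Observe a query's annotation multiplicities against a corpus.

    Every query gene must belong to the corpus — enrichment conditions on
    the query being part of the annotation universe.  Duplicate genes are
    collapsed: the hypergeometric model draws genes without replacement,
    so a multiset query is not observable (a self-pair reduces to n = 1).
    """
    if not genes:
        raise ValueError("query gene list is empty")
    genes = tuple(dict.fromkeys(genes))
    term_sets = []
    for g in genes:
        if g not in corpus.gene_terms:
            raise UnknownGeneError(g)
        term_sets.append(corpus.gene_terms[g])
    ctx = QueryContext.from_term_sets(term_sets, genes=tuple(genes))
    return ctx


def hypergeom_pmf(k: int, n: int, M: int, N: int) -> float:
    """P(k of n sampled genes annotated | M of N corpus genes annotated).

    ``C(M, k) * C(N - M, n - k) / C(N, n)`` with the convention
    ``C(a, b) = 0`` for ``b > a``; exact up to float rounding.
    """
    if not (0 <= k <= n <= N and 0 <= M <= N):
        raise ValueError(
            f"hypergeometric bounds violated: k={k}, n={n}, M={M}, N={N}"
        )
    if k > M or n - k > N - M:
        return 0.0
    return math.comb(M, k) * math.comb(N - M, n - k) / math.comb(N, n)


def enriched_ic(base_ic: float, k: int, n: int, M: int, N: int) -> float:
    """``IC*(t) = -log p(k, n | t) + IC(t)``; always >= the base IC."""
    pmf = hypergeom_pmf(k, n, M, N)
    if pmf == 0.0:
        raise InconsistentContextError(
            f"annotation context (k={k}, n={n}, M={M}, N={N}) has "
            "hypergeometric probability 0"
        )
    return -math.log(pmf) + base_ic


def enriched_ic_pair_partial(base_ic: float, M: int, N: int) -> float:
    """Closed form for a pair query with partial annotation (n=2, k=1):

    ``IC* = -log(2 M (N - M) / (N (N - 1))) + IC``.
    """
    if not 1 <= M <= N - 1:
        raise InconsistentContextError(
            f"partial annotation needs 1 <= M <= N-1 (M={M}, N={N})"
        )
    return -math.log(2 * M * (N - M) / (N * (N - 1))) + base_ic


def enriched_ic_pair_full(base_ic: float, M: int, N: int) -> float:
    """Closed form for a pair query with complete annotation (n=2, k=2):

    ``IC* = -log(M (M - 1) / (N (N - 1))) + IC``.
    """
    if not 2 <= M <= N:
        raise InconsistentContextError(
            f"complete annotation needs 2 <= M <= N (M={M}, N={N})"
        )
    return -math.log(M * (M - 1) / (N * (N - 1))) + base_ic


def enriched_ic_table(
    base: ICTable,
    corpus: AnnotationCorpus,
    ctx: QueryContext,
    strict: bool = False,
) -> ICTable:
    """Enrich a whole IC table against one query context.

    Terms observed in the query (k >= 1) get the hypergeometric
    correction; terms with k = 0 keep their base IC by default — they
    only enter similarity formulas as ancestors of annotated terms.
    ``strict=True`` applies the k = 0 correction too.
    """
    n_corpus = corpus.n_genes
    ic: dict[str, float] = {}
    for term, base_ic in base.ic.items():
        k = ctx.k.get(term, 0)
        if k == 0 and not strict:
            ic[term] = base_ic
            continue
        ic[term] = enriched_ic(base_ic, k, ctx.n, corpus.count(term), n_corpus)
    meta = dict(base.meta)
    meta["query"] = ",".join(ctx.genes)
    return ICTable(model=base.model + "*", ic=ic, meta=meta)


def classify_pair_terms(
    ctx: QueryContext,
    restrict_to: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Split a pair context's terms into (complete, partial) annotation.

    Complete terms annotate both query genes (k = 2), partial terms
    exactly one (k = 1).  ``restrict_to`` limits the report, e.g. to the
    directly annotated terms.
    """
    if ctx.n != 2:
        raise ValueError("partial/complete classification is defined for gene pairs")
    universe = set(ctx.k) if restrict_to is None else set(restrict_to)
    complete = {t for t in universe if ctx.k.get(t, 0) == 2}
    partial = {t for t in universe if ctx.k.get(t, 0) == 1}
    return complete, partial
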