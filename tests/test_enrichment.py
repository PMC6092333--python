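"""Hypergeometric annotation model and enriched IC."""

import math
from fractions import Fraction
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gofunsim.enrichment import (
    build_context,
    classify_pair_terms,
    enriched_ic,
    enriched_ic_pair_full,
    enriched_ic_pair_partial,
    enriched_ic_table,
    hypergeom_pmf,
)
from gofunsim.exceptions import InconsistentContextError, UnknownGeneError
from gofunsim.ic import ic_corpus

from conftest import small_study


def test_pmf_by_exhaustive_enumeration():
    # N=4 genes, M=2 annotated; draw n=2: count draws with exactly k hits
    genes = range(4)
    annotated = {0, 1}
    draws = list(combinations(genes, 2))
    for k in (0, 1, 2):
        count = sum(1 for d in draws if len(annotated & set(d)) == k)
        assert hypergeom_pmf(k, 2, 2, 4) == pytest.approx(
            float(Fraction(count, len(draws))), abs=1e-15
        )
    assert hypergeom_pmf(1, 2, 2, 4) == pytest.approx(2 / 3, abs=1e-15)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(data=st.data())
def test_pmf_normalizes_for_any_valid_parameters(data):
    n_corpus = data.draw(st.integers(1, 500))
    m = data.draw(st.integers(0, n_corpus))
    n = data.draw(st.integers(1, min(n_corpus, 8)))
    total = sum(hypergeom_pmf(k, n, m, n_corpus) for k in range(n + 1))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_pmf_degenerate_and_bounds():
    assert hypergeom_pmf(2, 2, 10, 10) == 1.0  # all genes annotated
    assert hypergeom_pmf(2, 2, 1, 10) == 0.0  # impossible draw
    with pytest.raises(ValueError):
        hypergeom_pmf(3, 2, 5, 10)
    with pytest.raises(ValueError):
        hypergeom_pmf(0, 2, 11, 10)


def test_pmf_matches_scipy(rng):
    for _ in range(300):
        n_corpus = int(rng.integers(2, 400))
        m = int(rng.integers(0, n_corpus + 1))
        n = int(rng.integers(1, min(n_corpus, 6) + 1))
        k = int(rng.integers(0, n + 1))
        ours = hypergeom_pmf(k, n, m, n_corpus)
        ref = stats.hypergeom.pmf(k, n_corpus, m, n)
        assert ours == pytest.approx(float(ref), abs=1e-12)


def test_enriched_ic_hand_value_and_dominance(rng):
    # -log(2/3) + log 2 = log 3
    assert enriched_ic(math.log(2), 1, 2, 2, 4) == pytest.approx(math.log(3))
    for _ in range(500):
        n_corpus = int(rng.integers(2, 200))
        m = int(rng.integers(1, n_corpus + 1))
        n = int(rng.integers(1, min(n_corpus, 5) + 1))
        lo, hi = max(0, n - (n_corpus - m)), min(n, m)
        k = int(rng.integers(lo, hi + 1))
        base = float(rng.uniform(0, 5))
        star = enriched_ic(base, k, n, m, n_corpus)
        assert star >= base - 1e-12
        if hypergeom_pmf(k, n, m, n_corpus) == 1.0:
            assert star == base


def test_pair_closed_forms_match_general():
    for n_corpus in range(2, 60):
        for m in range(1, n_corpus):
            assert enriched_ic_pair_partial(0.7, m, n_corpus) == pytest.approx(
                enriched_ic(0.7, 1, 2, m, n_corpus), abs=1e-12
            )
        for m in range(2, n_corpus + 1):
            assert enriched_ic_pair_full(0.7, m, n_corpus) == pytest.approx(
                enriched_ic(0.7, 2, 2, m, n_corpus), abs=1e-12
            )
    assert enriched_ic_pair_full(1.3, 10, 10) == pytest.approx(1.3)  # M=N
    with pytest.raises(InconsistentContextError):
        enriched_ic_pair_partial(0.0, 10, 10)
    with pytest.raises(InconsistentContextError):
        enriched_ic_pair_full(0.0, 1, 10)


def test_rare_terms_gain_more_from_complete_annotation():
    # for M <= (N-1)/3 the complete-annotation IC gain beats the partial one
    for n_corpus in (10, 31, 100):
        for m in range(2, (n_corpus - 1) // 3 + 1):
            full_gain = enriched_ic_pair_full(0.0, m, n_corpus)
            partial_gain = enriched_ic_pair_partial(0.0, m, n_corpus)
            assert full_gain > partial_gain


def test_build_context_counts_and_errors(frozen):
    dag, corpus = frozen
    ctx = build_context(corpus, ("P01906", "P17693"))
    assert ctx.n == 2
    assert ctx.k["GO:0006955"] == 2 and ctx.k["GO:0019882"] == 2
    for t in ("GO:0002504", "GO:0002474", "GO:0006968"):
        assert ctx.k[t] == 1
    assert ctx.k[dag.roots["BP"]] == 2
    with pytest.raises(UnknownGeneError):
        build_context(corpus, ("P01906", "nope"))
    solo = build_context(corpus, ("Q00002",))
    assert solo.n == 1 and set(solo.k) == set(corpus.gene_terms["Q00002"])
    # duplicate genes collapse: a self-pair is an n=1 query
    assert build_context(corpus, ("P01906", "P01906")).n == 1


def test_context_recount_oracle(rng):
    _, corpus = small_study(71)
    genes = corpus.genes
    g1, g2 = genes[0], genes[1]
    ctx = build_context(corpus, (g1, g2))
    for t, k in ctx.k.items():
        assert k == sum(t in corpus.gene_terms[g] for g in (g1, g2))
    assert all(t in ctx.k for t in corpus.gene_terms[g1])


def test_classify_pair_terms(frozen):
    dag, corpus = frozen
    ctx = build_context(corpus, ("P01906", "P17693"))
    direct = corpus.direct_gene_terms["P01906"] | corpus.direct_gene_terms["P17693"]
    complete, partial = classify_pair_terms(ctx, restrict_to=direct)
    assert complete == {"GO:0006955", "GO:0019882"}
    assert partial == {"GO:0002504", "GO:0002474", "GO:0006968"}


def test_enriched_table_recomputation_and_strict(frozen):
    dag, corpus = frozen
    base = ic_corpus(corpus)
    ctx = build_context(corpus, ("P01906", "P17693"))
    table = enriched_ic_table(base, corpus, ctx)
    for t, value in table.ic.items():
        k = ctx.k.get(t, 0)
        if k == 0:
            assert value == base.ic[t]
        else:
            assert value == pytest.approx(
                enriched_ic(base.ic[t], k, 2, corpus.count(t), corpus.n_genes)
            )
            assert value >= base.ic[t]
    # strict mode also corrects unobserved terms with k = 0
    solo_ctx = build_context(corpus, ("Q00002",))
    strict = enriched_ic_table(base, corpus, solo_ctx, strict=True)
    unobserved = [t for t in base.ic if t not in solo_ctx.k and corpus.count(t) < corpus.n_genes]
    assert unobserved and all(strict.ic[t] > base.ic[t] for t in unobserved)


def test_observed_contexts_are_always_consistent():
    # k(t) <= M(t) after propagation, so the pmf is positive on any
    # context built from corpus members
    _, corpus = small_study(72)
    genes = corpus.genes
    for g1, g2 in zip(genes[:8], genes[8:16]):
        ctx = build_context(corpus, (g1, g2))
        for t, k in ctx.k.items():
            assert hypergeom_pmf(k, ctx.n, corpus.count(t), corpus.n_genes) > 0
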