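"""Gene-level measures: registry, combiners, engine, disease scoring."""

import io
import math
from dataclasses import replace

import numpy as np
import pytest

from gofunsim.annotations import parse_tsv, propagate
from gofunsim.exceptions import DegenerateInputError, RegistryError
from gofunsim.funsim import (
    DIRECT_COMBINERS,
    PAIR_COMBINERS,
    REGISTRY_ROWS,
    FunSimEngine,
    MeasureSpec,
    combine_direct,
    combine_pairwise,
    combine_set,
    disease_association,
    funsim,
    list_measures,
)
from gofunsim.ic import ICTable, ic_corpus
from gofunsim.ontology import parse_obo

from conftest import small_study


def test_registry_enumerates_46_with_row_structure():
    specs = list_measures()
    assert len(specs) == 46
    assert len(set(specs)) == 46
    by_row = {}
    for s in specs:
        by_row.setdefault(s.ic_model, set()).add(s.combiner)
    assert {r: len(c) for r, c in by_row.items()} == {
        "U": 7, "Z": 7, "W": 7, "N": 4, "XN": 4, "L": 4, "XL": 4, "S": 4,
        "D": 3, "R": 1, "I": 1,
    }
    assert by_row["R"] == {"OR"} and by_row["I"] == {"IUR"}
    assert len(list_measures(enriched_variants=True)) == 92


def test_registry_rejects_invalid_rows():
    with pytest.raises(RegistryError):
        MeasureSpec("D", "BMA")
    with pytest.raises(RegistryError):
        MeasureSpec("L", "GIC")
    with pytest.raises(RegistryError):
        MeasureSpec("R", "IUR")
    spec = MeasureSpec.parse("XN_BMA*")
    assert spec == MeasureSpec("XN", "BMA", enriched=True)
    assert spec.name == "XN_BMA*"


def test_combine_direct_conventions_and_oracle(rng):
    ic = ICTable(model="corpus", ic={c: float(i) for i, c in enumerate("abcdef")})
    t1, t2 = {"b", "c", "d"}, {"c", "d", "e", "f"}
    inter = sum(ic.ic[t] for t in t1 & t2)
    assert combine_direct("GIC", ic, t1, t2) == pytest.approx(
        inter / sum(ic.ic[t] for t in t1 | t2)
    )
    assert combine_direct("DIC", ic, t1, t2) == pytest.approx(
        2 * inter / (sum(ic.ic[t] for t in t1) + sum(ic.ic[t] for t in t2))
    )
    assert combine_direct("UIC", ic, t1, t2) == pytest.approx(
        inter / max(sum(ic.ic[t] for t in t1), sum(ic.ic[t] for t in t2))
    )
    for kind in DIRECT_COMBINERS:
        assert combine_direct(kind, ic, t1, t1) == 1.0
        assert combine_direct(kind, ic, {"b"}, {"c"}) == 0.0  # disjoint
        assert combine_direct(kind, ic, {"a"}, {"a"}) == 1.0  # zero-IC sets


def test_combine_pairwise_hand_values(rng):
    m = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert combine_pairwise("AVG", m) == 0.5
    assert combine_pairwise("MAX", m) == 1.0
    assert combine_pairwise("BMA", m) == 1.0
    assert combine_pairwise("ABM", m) == 1.0
    single = np.array([[0.37]])
    for kind in PAIR_COMBINERS:
        assert combine_pairwise(kind, single) == pytest.approx(0.37)
    with pytest.raises(DegenerateInputError):
        combine_pairwise("AVG", np.array([[np.nan]]))
    # brute-force definitions on random rectangular matrices
    for _ in range(20):
        sims = rng.uniform(size=(3, 4))
        assert combine_pairwise("AVG", sims) == pytest.approx(sims.mean())
        assert combine_pairwise("MAX", sims) == pytest.approx(sims.max())
        rmax = [max(row) for row in sims]
        cmax = [max(col) for col in sims.T]
        assert combine_pairwise("BMA", sims) == pytest.approx(
            0.5 * (sum(rmax) / 3 + sum(cmax) / 4)
        )
        assert combine_pairwise("ABM", sims) == pytest.approx(
            (sum(rmax) + sum(cmax)) / 7
        )


def test_bma_and_abm_differ_on_rectangular_input(rng):
    sims = rng.uniform(size=(2, 5))
    assert combine_pairwise("BMA", sims) != pytest.approx(
        combine_pairwise("ABM", sims)
    )


def test_combine_set_nested_and_disjoint():
    ic_by_set = {
        frozenset({"a"}): 2.0,
        frozenset({"a", "b"}): 5.0,
    }
    fn = lambda terms: ic_by_set[frozenset(terms)]
    # nested T1 subset of T2: OR = (1 + IC(T1)/IC(T2))/2
    assert combine_set("OR", fn, {"a"}, {"a", "b"}) == pytest.approx(
        0.5 * (1.0 + 2.0 / 5.0)
    )
    assert combine_set("IUR", fn, {"a"}, {"a", "b"}) == pytest.approx(2.0 / 5.0)
    assert combine_set("OR", fn, {"a"}, {"b"}) == 0.0
    assert combine_set("IUR", fn, {"a", "b"}, {"a", "b"}) == 1.0


def test_funsim_l_avg_matches_hand_expansion(toy):
    dag, corpus = toy
    res = funsim(MeasureSpec("L", "AVG"), corpus, dag, "g1", "g2")
    # hand expansion over the propagated sets {root,p,t1} x {root,p,t2}
    # with corpus ICs root=0, p=log2, t1=t2=log4 and MICAs read off the DAG
    log2, log4 = math.log(2), math.log(4)
    lin = {
        ("GO:0000001", "GO:0000001"): 1.0,  # both roots: 0/0 convention
        ("GO:0000001", "GO:0000002"): 0.0,
        ("GO:0000001", "GO:0000004"): 0.0,
        ("GO:0000002", "GO:0000001"): 0.0,
        ("GO:0000002", "GO:0000002"): 1.0,
        ("GO:0000002", "GO:0000004"): 2 * log2 / (log2 + log4),
        ("GO:0000003", "GO:0000001"): 0.0,
        ("GO:0000003", "GO:0000002"): 2 * log2 / (log4 + log2),
        ("GO:0000003", "GO:0000004"): 2 * log2 / (log4 + log4),
    }
    assert res.score == pytest.approx(sum(lin.values()) / 9)
    assert res.terms_used == {"common": 2, "only_first": 1, "only_second": 1}


def test_normalized_measures_self_similarity_and_symmetry():
    dag, corpus = small_study(81, n_genes=10)
    engine = FunSimEngine(dag, corpus)
    genes = corpus.genes
    for spec in list_measures(enriched_variants=True):
        s12 = engine.score(spec, genes[0], genes[1]).score
        s21 = engine.score(spec, genes[1], genes[0]).score
        assert s12 == pytest.approx(s21, abs=1e-12), spec.name
        if spec.normalized:
            assert engine.score(spec, genes[2], genes[2]).score == pytest.approx(
                1.0
            ), spec.name


def test_enrichment_separates_rare_from_common_sharing():
    # g1,g2 share a rare term (M=2 of N=8); g3,g4 share only universal
    # terms; each gene carries one unique term
    dag = parse_obo(io.StringIO(
        "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: root\n"
        "namespace: biological_process\n"
        "\n[Term]\nid: GO:0000002\nname: common\nnamespace: biological_process\n"
        "is_a: GO:0000001\n"
        "\n[Term]\nid: GO:0000003\nname: rare\nnamespace: biological_process\n"
        "is_a: GO:0000002\n"
        + "".join(
            f"\n[Term]\nid: GO:000001{i}\nname: unique {i}\n"
            "namespace: biological_process\nis_a: GO:0000002\n"
            for i in range(8)
        )
    ))
    rows = []
    for i, gene in enumerate(["g1", "g2", "g3", "g4", "g5", "g6", "g7", "g8"]):
        rows.append(f"{gene}\tGO:000001{i}")
        rows.append(f"{gene}\tGO:0000003" if gene in ("g1", "g2") else f"{gene}\tGO:0000002")
    corpus = propagate(dag, parse_tsv(io.StringIO("\n".join(rows) + "\n")), namespace="BP")
    assert corpus.count("GO:0000003") == 2 and corpus.count("GO:0000002") == 8
    engine = FunSimEngine(dag, corpus)
    gic = MeasureSpec("D", "GIC")
    gic_star = replace(gic, enriched=True)
    delta_rare = (
        engine.score(gic_star, "g1", "g2").score - engine.score(gic, "g1", "g2").score
    )
    delta_common = (
        engine.score(gic_star, "g3", "g4").score - engine.score(gic, "g3", "g4").score
    )
    assert delta_rare > delta_common


def test_disease_association_strategies():
    dag, corpus = small_study(82, n_genes=12)
    genes = corpus.genes
    spec = MeasureSpec("D", "GIC")
    # singleton disease set reduces to plain pair scoring
    single = disease_association(spec, corpus, dag, [genes[0]], genes[1])
    assert single.score == pytest.approx(
        funsim(spec, corpus, dag, genes[0], genes[1]).score
    )
    # the candidate itself as the only disease gene: unit similarity
    assert disease_association(
        MeasureSpec("D", "GIC", enriched=True), corpus, dag, [genes[0]], genes[0]
    ).score == pytest.approx(1.0)
    gd = genes[:4]
    pooled = disease_association(spec, corpus, dag, gd, genes[5])
    averaged = disease_association(spec, corpus, dag, gd, genes[5], strategy="average")
    assert pooled.strategy == "pool" and averaged.strategy == "average"
    # hand oracles for both strategies
    t_cand = corpus.gene_terms[genes[5]]
    pool_terms = frozenset().union(*(corpus.gene_terms[g] for g in gd))
    table = ic_corpus(corpus)
    s_int = sum(table.ic[t] for t in pool_terms & t_cand)
    s_uni = sum(table.ic[t] for t in pool_terms | t_cand)
    assert pooled.score == pytest.approx(s_int / s_uni)
    assert averaged.score == pytest.approx(
        np.mean([funsim(spec, corpus, dag, g, genes[5]).score for g in gd])
    )
    with pytest.raises(DegenerateInputError):
        disease_association(spec, corpus, dag, [], genes[5])


def test_enriched_disease_pooling_uses_gene_level_context():
    # overlapping disease set and candidate must not produce an
    # inconsistent hypergeometric context
    dag, corpus = small_study(83, n_genes=12)
    genes = corpus.genes
    spec = MeasureSpec("R", "OR", enriched=True)
    res = disease_association(spec, corpus, dag, genes[:3], genes[0])
    assert np.isfinite(res.score)
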