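# gofunsim

Gene Ontology (GO) functional similarity between genes, with a
query-conditional **enrichment correction** that augments each term's
information content by how the term is represented in the querying gene
pair or set.

## The problem

Functional similarity (FS) between two genes is computed from the GO
terms annotating them, via the information content (IC) of those terms.
Classical ICs come either from an annotation corpus — `IC(t) = −log
M(t)/N`, where `M(t)` of the `N` annotated genes carry term `t` — or
from the topology of the GO DAG (depth, children, ancestors).  Both
ignore the *local context*: whether a term annotates one gene of the
querying pair (partial annotation) or both (complete annotation).

gofunsim implements 46 established FS measures — eleven IC/SS families
(GO-universal, Zhang, Wang, Nunivers, extended Nunivers, Lin, extended
Lin, Schlicker, direct corpus IC, SORA, WIS) crossed with their
compatible combiners (AVG, MAX, BMA, ABM over term pairs; GIC, DIC, UIC
over term sets; OR, IUR over composed set-ICs) — plus the enriched
(starred) variant of every one of them.  The enrichment models the
annotation multiplicity `k` of a term within an `n`-gene query as a
hypergeometric draw from the corpus:

```
p(k, n | t) = C(M, k) · C(N−M, n−k) / C(N, n)
p*(t)       = p(k, n | t) · p(t)
IC*(t)      = −log p(k, n | t) + IC(t)   ≥  IC(t)
```

For a gene pair (`n = 2`) this has closed forms: partial annotation
(`k = 1`) adds `−log(2M(N−M)/(N(N−1)))`, complete annotation (`k = 2`)
adds `−log(M(M−1)/(N(N−1)))`.  Rare terms shared by both genes gain the
most IC, so measures that contrast common against unique terms separate
interacting pairs more sharply.  Substituting `IC*` for `IC` everywhere
downstream turns any `FS` into its enriched `FS*`.

The package is aimed at computational biologists scoring gene pairs,
benchmarking similarity measures, or prioritising candidate disease
genes by similarity to a known disease gene set.

## Worked example

The shipped worked example is a 7-term immune-response fragment
annotating two proteins: P01906 carries {immune response, antigen
processing and presentation, MHC-class-II presentation}; P17693 carries
{immune response, antigen processing and presentation, MHC-class-I
presentation, cellular defense response}.  Two terms annotate both
proteins, three annotate exactly one.

```console
$ gofunsim score --obo go.obo --annotations annotations.tsv \
    --pairs pairs.tsv --measure D_GIC --measure XN_BMA --measure R_OR
gene1   gene2   measure enriched        score
P01906  P17693  D_GIC   0       0.190833
P01906  P17693  XN_BMA  0       0.842293
P01906  P17693  R_OR    0       0.378462

$ gofunsim score ... --enriched
P01906  P17693  D_GIC   1       0.357143
P01906  P17693  XN_BMA  1       0.991721
P01906  P17693  R_OR    1       0.704327
```

`D_GIC` is the IC-weighted Jaccard index of the two propagated term
sets: 0.190833 says the shared terms carry ~19% of the pair's total IC.
Under enrichment the two completely annotated terms receive the large
`k = 2` correction (they are rare in this 4-gene corpus), roughly
doubling the shared-IC share (0.357143).  The same shift appears in the
best-match-average (`XN_BMA`) and set-IC overlap-ratio (`R_OR`) scores.

Other entry points: `gofunsim list-measures`, `gofunsim disease`
(disease-set vs candidate scoring), `gofunsim evaluate` (Pearson/AUC
plus Williams and Wilcoxon comparisons), `gofunsim synth` (write a
synthetic OBO/GAF/benchmark triple).

Library use mirrors the CLI:

```python
from gofunsim import FunSimEngine, MeasureSpec
from gofunsim.fixtures import frozen_pair_fixture

dag, corpus = frozen_pair_fixture()
engine = FunSimEngine(dag, corpus)
engine.score(MeasureSpec.parse("D_GIC*"), "P01906", "P17693").score
# 0.35714285714285715
```

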