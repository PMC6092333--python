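# Methods

## Ontology model

GO terms form a DAG per namespace (BP/MF/CC) with typed edges `is_a`,
`part_of` and `regulates` (the positively/negatively regulating
variants collapse onto `regulates`).  All three edge types contribute
to ancestry and annotation propagation by default; `parse_obo`'s
`relations=` argument restricts them (e.g. to drop `regulates` from
closures), since usage in the field varies.  Edge types are retained on
the graph because the Wang semantic weights depend on them.

**Depth** is the number of edges on the *longest* path from the
namespace root (root depth 0).  The alternative shortest-path depth
compresses deep terms onto few levels; the longest-path reading
maximises the discrimination of the depth-weighted structural ICs,
which is why it is the default here.

**Common ancestors are inclusive** of the query terms: a term is its
own most-informative common ancestor, which makes Lin/Nunivers
self-similarity exactly 1 and every normalized gene-level measure
satisfy FS(g, g) = 1.  Obsolete terms are retained but flagged,
stripped of parents, excluded from term totals, and dropped from all
computations with a logged warning; unresolved `alt_id`s likewise warn
rather than error.

## Annotation corpora

Corpora are loaded from GAF 2.x (rows filtered by namespace aspect,
`NOT` qualifiers dropped, evidence-code exclusion configurable and
empty by default — IEA annotations are kept) or from a plain
two-column TSV.  The true-path rule is applied eagerly: each gene's
term set becomes its inclusive ancestor closure, so `M(t)` (genes per
term) is monotone non-decreasing toward the root and `M(root) = N`.
Genes with no resolvable annotation in the chosen namespace are
excluded from `N`, which keeps `p(t) = M/N` a probability over the
annotated universe.

## Information content

All logarithms are natural; a fixed base rescales every IC jointly and
cancels in each normalised similarity.

* **corpus** — `IC(t) = −log(M(t)/N)`; defined only for corpus terms.
* **SORA** — `depth(t)·(1 − log(|C(t)|+1)/log T_total)`; leaves get
  their depth, the root 0.
* **WIS** — `depth(t)·log|A(t)|·(1 − log(Σ_{x∈C(t)∪{t}} 1/depth(x) +
  1)/log T_total)` with `A(t)` the strict ancestor set.  The root is
  forced to 0 and contributes no `1/depth` term; children of the root
  (`|A| = 1`) get 0 as the formula's literal consequence.
* **GO-universal** — `p(root) = 1`, `p(t) = Π_{x∈P(t)} p(x)/|C(x)|`
  in topological order, `IC = −log p`.  The recursion is purely
  topological; it is implemented exactly as printed in its source.
* **Zhang** — descendant mass `D(t)` (1 at leaves, child-sum inside),
  `p(t) = D(t)/D(root)`.  The defining reference gives the recursion;
  it is isolated behind the model name so it can be swapped.
* **Wang** — semantic-value profiles: `s_t(t) = 1` and `s_t(x)` the
  maximum over children `x′` of `x` on a path to `t` of
  `w(x→x′)·s_t(x′)` — the *recursive* best-path product (a
  non-recursive reading of the max would make the profile independent
  of `t` and collapse the measure).  Weights: 0.8 for `is_a`, 0.6 for
  `part_of`; `regulates` defaults to 0.6 and is configurable, since the
  classical weight table predates regulates edges.  `IC_wang(t)` is the
  profile total, always ≥ 1.

## Term-level similarity

The common-ancestor profile of a pair orders common ancestors by
non-increasing IC, ties broken lexicographically by term id so every
downstream value is deterministic.  On top of it:
Resnik (`IC(a0)`), Lin, Nunivers, Schlicker (Lin damped by
`1 − e^{−IC(a0)}`), Zhang (`e^{−IC(a0)}`), and the XGraSM-extended
Lin/Nunivers, which replace `IC(a0)` by the mean IC over all
*informative* common ancestors (defined here as IC > 0, which excludes
roots).  When the two terms both have IC 0, the normalised models
return 1 by convention (0/0 of identical roots); any other division by
zero raises.

Two properties of the printed formulas are kept deliberately and
flagged:

* the Zhang pair similarity **decreases** with the common-ancestor IC
  and saturates at 1 whenever the root is the MICA — combined with
  propagated term sets this makes Z_MAX/Z_BMA/Z_ABM saturate at 1 for
  most pairs;
* the XGraSM average is ≤ the MICA IC, so extended Lin/Nunivers are
  **≤** their base measures, and even their self-similarity sits below
  1.  Consequently XL/XN pairwise measures (like Schlicker's and every
  AVG) are outside the set of measures with guaranteed FS(g, g) = 1.

**Set IC (SORA/WIS composition).**  Over the sub-DAG induced by the
inclusive ancestor closure of a term set, each term contributes its
extended IC once: `IC(x) − max_{a∈P(x)∩closure} w(a→x)·IC(a)`, with
`w = 1` (SORA) or `w = |C(x)|/|C(a)|` (WIS); closure-roots contribute
their full IC.  The composition is stated in its source only for one
parent–child pair; crediting the single largest inherited IC at
multi-parent terms is the reading validated here against chain
telescoping (a singleton chain recovers `IC(t)` exactly under SORA
weights).  On DAGs with the WIS weights individual contributions can be
negative (a child with more children than its parent inherits more than
the parent's IC); the composition is used as printed.

## Query enrichment

A query of `n` distinct genes observes multiplicity `k(t)` = number of
query genes whose propagated set contains `t`.  Binomials use exact
integer arithmetic (`math.comb`), so the pmf is correct to float
rounding at any realistic corpus size; the independent oracle in the
tests is scipy's log-gamma-based hypergeometric.

Conventions:

* **Duplicate query genes collapse.**  The hypergeometric draw is
  without replacement, so a multiset query is not observable; a
  self-pair reduces to an `n = 1` query.  This keeps every observed
  context consistent (`k(t) ≤ M(t)` after propagation guarantees a
  positive pmf).
* **Terms with k = 0 keep their base IC** by default: they enter
  similarity formulas only as ancestors of annotated terms, and the
  propagation closure makes genuinely relevant ancestors k ≥ 1 anyway.
  `strict=True` applies the k = 0 correction as well.
* **Gene sets** (`n > 2`, used by disease association) apply the
  general-`n` correction directly; the pair closed forms are the
  `n = 2` specialisation and agree with the general formula to float
  precision over exhaustive grids.

Enriched measures substitute `IC*` wherever `IC` appears: per-term sums
in GIC/DIC/UIC, the IC table under every pairwise model (MICA selection
included), the set-IC composition, and the denominators of the Wang
pair similarity (whose numerator is built from semantic values, not
ICs — which is why enriched Wang pairwise scores are not guaranteed to
reach 1 at self-pairs).  Because IC* is not monotone along ancestry in
general, a few enriched pairwise scores can exceed 1; symmetry is
always preserved since the pair context is order-free.

## Gene-level measures and disease association

Genes are compared on propagated term sets throughout.  Registry rows
pair each IC family with its compatible combiners (7 each for
U/Z/W, 4 each for N/XN/L/XL/S, GIC/DIC/UIC for direct corpus IC, OR for
SORA, IUR for WIS): 46 measures, 92 with enriched variants.  The
corpus-IC rows (N/XN/L/XL/S/D) share one IC table; U/Z/W use their
namesake ICs inside both the pairwise similarity and the direct
combiners.

Two printed combiner forms are normalised to their standard readings:
ABM uses the `1/(|T1|+|T2|)` prefactor (the printed `1/(|T1||T2|)`
would contradict "average best matches" and make ABM ≠ BMA even on
square inputs for the wrong reason), and the BMA summands are read as
best-match values (row/column maxima) — the only reading that
distinguishes BMA from AVG.

Disease association scores FS(G_d, g).  The default pools the disease
genes' propagated sets into one pseudo-profile; the alternative
(`strategy="average"`) averages FS(x, g) over disease genes.  Under
enrichment the context is the set of distinct genes involved (disease
genes plus candidate) with the general-`n` correction: treating the
pool as a pseudo-gene in an `n = 2` context would fabricate
inconsistent observations (k = 2 with M = 1) whenever the candidate
overlaps the disease set.

## Evaluation statistics

* Pearson correlation (scipy), errors on constant input.
* ROC/AUC (scikit-learn), the Mann–Whitney probability of correct
  ranking with ties counted ½.
* **Williams test** for two dependent correlations sharing a
  reference:
  `t(n−3) = (r13 − r23)·√((n−1)(1+r12)) / √(2K(n−1)/(n−3) +
  ((r13+r23)/2)²(1−r12)³)`, `K` the determinant of the correlation
  matrix.  This is the standard form of the test; an alternate printed
  variant with a quarter-sum mean term is available behind
  `literal_variant=True` for comparison.  One-sided p from the t
  distribution; identical inputs short-circuit to t = 0, p = 0.5.
* **Wilcoxon signed rank**, one-sided, zeros dropped.  For n ≤ 25 the
  exact sign-flip distribution is computed by shift convolution over
  doubled midranks (exact even with tied magnitudes, where scipy's
  exact method is undefined); above that, the normal approximation with
  continuity correction.
* Benjamini–Hochberg adjustment via statsmodels.

## Synthetic data

The generators emulate what the methods are sensitive to, not GO's full
topology statistics:

* layered single-root DAGs with geometric layer growth, optional
  second parents, and mixed edge types (`part_of` fraction 0.2,
  `regulates` 0.05);
* corpora with power-law direct-annotation popularity (exponent 1.5),
  shallow terms most popular, ~4 direct annotations per gene — the
  heavy-tailed regime in which partial- and complete-annotation
  corrections differ most;
* overlap benchmarks (`reference = signal·GIC + (1−signal)·noise`,
  labels by median split, classes balanced by construction) and an
  interaction-style benchmark whose positive pairs are co-annotated to
  a rare term (2 ≤ M ≤ max(3, N/20)) with equally many random negative
  pairs.

Default study conditions: 120 terms over 6 levels, 150 genes, 120
benchmark pairs, 20 seeds for the plain-vs-enriched AUC comparison —
sizes at which every computation is exact and the whole pipeline runs
in seconds.  What passing tests show is that the implementation is
faithful and that the directional claim (enrichment helps when
interacting pairs share rare terms) holds in the regime constructed to
exhibit it; they do not certify effect sizes on real corpora, where
annotation noise, evidence-code composition and incomplete propagation
of curation practice all intervene.

The frozen worked example (7 terms, 4 genes, proteins P01906/P17693
with 2 completely and 3 partially annotated direct terms) uses real GO
accessions and names with a simplified edge set; it is synthetic in
every other respect.

## Known limitations

* Cross-namespace similarity is out of scope; pairs must share a
  namespace.
* The Zhang pair-similarity saturation and the XGraSM sub-unit
  self-similarity (above) are properties of the printed formulas, kept
  as-is.
* Structure-based ICs (SORA/WIS) are not monotone along ancestry, so
  MICA under them can sit below both query terms; ratios are still
  well-defined but interpretability differs from corpus IC.
* Enrichment conditions on the query genes being part of the corpus;
  scoring a gene absent from the annotation universe is an error, not a
  fallback.
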