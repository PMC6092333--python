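"""Deterministic synthetic data: toy DAGs, corpora and benchmark pair lists.

Everything the package needs for testing and demonstration is generated
here, with no downloads.  The generators emulate the salient features of
real GO data:

* a layered, single-root DAG with mixed is_a/part_of/regulates edges;
* an annotation corpus with heavy-tailed term usage — a few terms
  annotate many genes, most annotate few (a discrete power law over
  direct-annotation popularity, shallow terms the most popular);
* benchmark pair lists whose continuous reference correlates with
  term-set overlap, and a protein-interaction-style variant in which
  interacting pairs share *rare* terms — the regime in which the
  complete-annotation enrichment gain is largest.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import IO

import numpy as np

from .annotations import AnnotationCorpus, parse_tsv, propagate
from .funsim import FunSimEngine, MeasureSpec
from .ontology import GODag, GOTerm, parse_obo

__all__ = [
    "FixtureSpec",
    "synth_dag",
    "synth_corpus",
    "write_gaf",
    "Benchmark",
    "synth_benchmark",
    "synth_rare_sharing_benchmark",
    "frozen_pair_fixture",
    "FROZEN_PAIR",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic-data generators.

    Defaults describe a small but non-trivial study: a 6-level DAG of
    120 terms, 150 annotated genes drawing ~4 direct annotations each
    from a power-law popularity distribution (exponent 1.5), and
    120-pair benchmarks.
    """

    seed: int = 0
    n_terms: int = 120
    n_levels: int = 6
    branching: float = 2.0
    part_of_fraction: float = 0.2
    regulates_fraction: float = 0.05
    extra_parent_prob: float = 0.3
    n_genes: int = 150
    annotations_per_gene: float = 4.0
    popularity_exponent: float = 1.5
    n_pairs: int = 120
    signal: float = 0.8
    namespace: str = "BP"

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("a layered DAG needs at least 2 levels")
        if self.n_terms < self.n_levels:
            raise ValueError(
                f"{self.n_terms} terms cannot fill {self.n_levels} levels"
            )
        if not 0.0 <= self.part_of_fraction <= 1.0:
            raise ValueError("part_of_fraction must lie in [0, 1]")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def synth_dag(spec: FixtureSpec) -> GODag:
    """Layered random DAG: single root, every non-root term parented in a
    strictly upper layer, mixed edge types, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n_inner = spec.n_terms - 1
    n_layers = spec.n_levels - 1
    # layer sizes grow geometrically with the branching factor
    weights = np.array([spec.branching**i for i in range(n_layers)])
    sizes = np.maximum(1, np.floor(n_inner * weights / weights.sum()).astype(int))
    while sizes.sum() > n_inner:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_inner:
        sizes[np.argmax(weights)] += 1
    root = _term_id(1)
    layers: list[list[str]] = [[root]]
    next_id = 2
    for size in sizes:
        layers.append([_term_id(next_id + j) for j in range(size)])
        next_id += size
    rel_p = np.array(
        [
            1.0 - spec.part_of_fraction - spec.regulates_fraction,
            spec.part_of_fraction,
            spec.regulates_fraction,
        ]
    )
    rels = np.array(["is_a", "part_of", "regulates"])
    terms: dict[str, GOTerm] = {
        root: GOTerm(id=root, name="synthetic root", namespace=spec.namespace)
    }
    for level, layer in enumerate(layers[1:], start=1):
        prev = layers[level - 1]
        upper = [t for lay in layers[:level] for t in lay]
        for tid in layer:
            parents = [(prev[rng.integers(len(prev))], str(rng.choice(rels, p=rel_p)))]
            if len(upper) > 1 and rng.random() < spec.extra_parent_prob:
                extra = upper[rng.integers(len(upper))]
                if extra != parents[0][0]:
                    parents.append((extra, str(rng.choice(rels, p=rel_p))))
            terms[tid] = GOTerm(
                id=tid,
                name=f"synthetic term {tid[3:]}",
                namespace=spec.namespace,
                parents=parents,
            )
    return GODag(terms)


def synth_corpus(dag: GODag, spec: FixtureSpec) -> AnnotationCorpus:
    """Annotation corpus with power-law term popularity.

    Direct annotations are drawn without replacement per gene, with
    probability proportional to ``rank^(-exponent)`` where shallower
    terms hold the top popularity ranks (as in real GOA corpora) while
    most deep terms annotate only a handful of genes.
    """
    rng = np.random.default_rng(spec.seed + 1)
    root = dag.roots[spec.namespace]
    candidates = sorted(t for t in dag.terms if t != root)
    depth_key = np.array([dag.depth[t] for t in candidates], dtype=float)
    # noisy depth ordering: popular terms sit high in the hierarchy
    order = np.argsort(depth_key + rng.normal(0, 0.75, len(candidates)))
    weights = np.zeros(len(candidates))
    weights[order] = (np.arange(1, len(candidates) + 1)) ** (
        -spec.popularity_exponent
    )
    weights /= weights.sum()
    raw: dict[str, set[str]] = {}
    for i in range(spec.n_genes):
        gene = f"G{i + 1:04d}"
        n_annot = 1 + rng.poisson(max(spec.annotations_per_gene - 1.0, 0.0))
        n_annot = min(n_annot, len(candidates))
        chosen = rng.choice(len(candidates), size=n_annot, replace=False, p=weights)
        raw[gene] = {candidates[j] for j in chosen}
    return propagate(dag, raw, namespace=spec.namespace)


_ASPECT = {"BP": "P", "MF": "F", "CC": "C"}


def write_gaf(corpus: AnnotationCorpus, stream: IO[str]) -> None:
    """Serialise a corpus's *direct* annotations as GAF 2.2."""
    stream.write("!gaf-version: 2.2\n")
    aspect = _ASPECT[corpus.namespace]
    for gene in sorted(corpus.direct_gene_terms):
        for term in sorted(corpus.direct_gene_terms[gene]):
            cols = [
                "SYNTH", gene, gene, "", term, "SYNTH:0000001", "IEA", "",
                aspect, gene, "", "protein", "taxon:0000", "20180814",
                "SYNTH", "", "",
            ]
            stream.write("\t".join(cols) + "\n")


@dataclass
class Benchmark:
    """A pair list with a continuous reference and binary labels."""

    pairs: list[tuple[str, str]]
    reference: np.ndarray
    labels: np.ndarray

    def to_tsv(self, stream: IO[str]) -> None:
        stream.write("gene1\tgene2\treference\tlabel\n")
        for (g1, g2), ref, lab in zip(self.pairs, self.reference, self.labels):
            stream.write(f"{g1}\t{g2}\t{ref:.6g}\t{int(lab)}\n")

    @classmethod
    def from_tsv(cls, stream: IO[str]) -> "Benchmark":
        pairs, refs, labs = [], [], []
        header = True
        for line in stream:
            if header:
                header = False
                continue
            g1, g2, ref, lab = line.rstrip("\n").split("\t")
            pairs.append((g1, g2))
            refs.append(float(ref))
            labs.append(int(lab))
        return cls(pairs=pairs, reference=np.array(refs), labels=np.array(labs))


def synth_benchmark(
    dag: GODag, corpus: AnnotationCorpus, spec: FixtureSpec
) -> Benchmark:
    """Benchmark whose reference tracks term-set overlap.

    ``reference = signal * (IC-weighted Jaccard of the term sets) +
    (1 - signal) * uniform noise``; binary labels threshold the
    reference at its median, so classes are balanced by construction.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = corpus.genes
    engine = FunSimEngine(dag, corpus)
    gic = MeasureSpec("D", "GIC")
    pairs: list[tuple[str, str]] = []
    overlap = np.empty(spec.n_pairs)
    for i in range(spec.n_pairs):
        g1, g2 = rng.choice(len(genes), size=2, replace=False)
        pair = (genes[g1], genes[g2])
        pairs.append(pair)
        overlap[i] = engine.score(gic, *pair).score
    noise = rng.uniform(size=spec.n_pairs)
    reference = spec.signal * overlap + (1.0 - spec.signal) * noise
    labels = (reference > np.median(reference)).astype(int)
    return Benchmark(pairs=pairs, reference=reference, labels=labels)


def synth_rare_sharing_benchmark(
    dag: GODag, corpus: AnnotationCorpus, spec: FixtureSpec
) -> Benchmark:
    """Interaction-style benchmark where positive pairs share rare terms.

    Positive pairs are two genes co-annotated (after propagation) to a
    rare term (2 <= M(t) <= max(3, N/20)); negatives are random
    annotated pairs, equally many.  The reference column repeats the
    labels (interaction benchmarks are binary).
    """
    rng = np.random.default_rng(spec.seed + 3)
    genes = corpus.genes
    n_half = spec.n_pairs // 2
    rare_cap = max(3, corpus.n_genes // 20)
    rare_terms = sorted(
        t for t, g in corpus.term_genes.items() if 2 <= len(g) <= rare_cap
    )
    if not rare_terms:
        raise ValueError("corpus has no rare co-annotating terms; enlarge it")
    pairs: list[tuple[str, str]] = []
    for _ in range(n_half):
        t = rare_terms[rng.integers(len(rare_terms))]
        members = sorted(corpus.term_genes[t])
        i, j = rng.choice(len(members), size=2, replace=False)
        pairs.append((members[i], members[j]))
    for _ in range(n_half):
        i, j = rng.choice(len(genes), size=2, replace=False)
        pairs.append((genes[i], genes[j]))
    labels = np.array([1] * n_half + [0] * n_half)
    return Benchmark(pairs=pairs, reference=labels.astype(float), labels=labels)


# ---------------------------------------------------------------------------
# frozen worked example: two proteins with common and unique terms

#: OBO text of a 7-term immune-response fragment; GO accessions and names
#: follow the public ontology, the edge set is simplified to a small DAG.
FROZEN_OBO = """\
format-version: 1.2
ontology: gofunsim-frozen-example

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0002376
name: immune system process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0006955
name: immune response
namespace: biological_process
is_a: GO:0002376

[Term]
id: GO:0019882
name: antigen processing and presentation
namespace: biological_process
is_a: GO:0002376

[Term]
id: GO:0002504
name: antigen processing and presentation of peptide or polysaccharide antigen via MHC class II
namespace: biological_process
is_a: GO:0019882

[Term]
id: GO:0002474
name: antigen processing and presentation of peptide antigen via MHC class I
namespace: biological_process
is_a: GO:0019882

[Term]
id: GO:0006968
name: cellular defense response
namespace: biological_process
is_a: GO:0006955
"""

#: direct annotations: the first protein carries the class-II
#: presentation term, the second the class-I and cellular-defense terms;
#: both share immune response and antigen processing/presentation.  Two
#: background genes pad the corpus.
FROZEN_TSV = """\
P01906\tGO:0006955
P01906\tGO:0019882
P01906\tGO:0002504
P17693\tGO:0006955
P17693\tGO:0019882
P17693\tGO:0002474
P17693\tGO:0006968
Q00001\tGO:0002376
Q00002\tGO:0006955
"""

#: the frozen query pair
FROZEN_PAIR = ("P01906", "P17693")


def frozen_pair_fixture() -> tuple[GODag, AnnotationCorpus]:
    """The canonical worked example: 7 terms, 4 genes, one query pair
    with 2 completely and 3 partially annotated direct terms."""
    dag = parse_obo(io.StringIO(FROZEN_OBO))
    raw = parse_tsv(io.StringIO(FROZEN_TSV))
    return dag, propagate(dag, raw, namespace="BP")


def default_study(seed: int, **overrides) -> tuple[GODag, AnnotationCorpus, FixtureSpec]:
    """One seeded DAG + corpus under the default study conditions."""
    spec = replace(FixtureSpec(), seed=seed, **overrides)
    dag = synth_dag(spec)
    corpus = synth_corpus(dag, spec)
    return dag, corpus, spec
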