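"""Per-term information content under six IC models.

Two families are covered:

* corpus-based — ``IC(t) = -log(M(t)/N)`` from annotation frequency;
* structure-based — SORA and WIS (depth/children formulas), the
  GO-universal topological recursion, Zhang's descendant-count
  probability, and Wang's semantic-value profiles.

All logarithms are natural: a fixed base only rescales every IC jointly
and cancels in each normalised similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Mapping

from .annotations import AnnotationCorpus
from .exceptions import DegenerateDagError, UnknownTermError
from .ontology import GODag

#: Wang semantic weights per edge type.  The is_a/part_of values are the
#: conventional 0.8/0.6; regulates edges default to the part_of weight.
DEFAULT_WANG_WEIGHTS: dict[str, float] = {
    "is_a": 0.8,
    "part_of": 0.6,
    "regulates": 0.6,
}

IC_MODELS = ("corpus", "sora", "wis", "go_universal", "zhang", "wang")


@dataclass
class ICTable:
    """Map term id -> information content under a named model."""

    model: str
    ic: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, term_id: str) -> float:
        try:
            return self.ic[term_id]
        except KeyError:
            raise UnknownTermError(
                f"no {self.model} IC entry for term {term_id}"
            ) from None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def get(self, term_id: str, default: float | None = None) -> float | None:
        return self.ic.get(term_id, default)

    def to_tsv(self, stream: IO[str]) -> None:
        stream.write(f"# model={self.model}")
        for key, value in sorted(self.meta.items()):
            stream.write(f" {key}={value}")
        stream.write("\nterm\tic\n")
        for term in sorted(self.ic):
            stream.write(f"{term}\t{self.ic[term]:.10g}\n")

    @classmethod
    def from_tsv(cls, stream: IO[str]) -> "ICTable":
        model = "unknown"
        meta: dict = {}
        ic: dict[str, float] = {}
        for line in stream:
            line = line.strip()
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, value = token.partition("=")
                    if key == "model":
                        model = value
                    elif value:
                        meta[key] = value
                continue
            if not line or line.startswith("term\t"):
                continue
            term, value = line.split("\t")
            ic[term] = float(value)
        return cls(model=model, ic=ic, meta=meta)


def _namespace_terms(dag: GODag, namespace: str) -> list[str]:
    return [
        t.id
        for t in dag.terms.values()
        if not t.obsolete and t.namespace == namespace
    ]


def _check_t_total(dag: GODag, namespace: str) -> int:
    t_total = dag.t_total.get(namespace, 0)
    if t_total <= 1:
        raise DegenerateDagError(
            f"namespace {namespace} has {t_total} terms; structure-based IC "
            "needs log(T_total) > 0"
        )
    return t_total


def ic_corpus(corpus: AnnotationCorpus) -> ICTable:
    """Annotation-frequency IC: ``-log(M(t)/N)`` over all corpus terms."""
    n = corpus.n_genes
    ic = {t: -math.log(len(genes) / n) for t, genes in corpus.term_genes.items()}
    return ICTable(model="corpus", ic=ic, meta={"N": n})


def ic_sora(dag: GODag, namespace: str = "BP") -> ICTable:
    """SORA structural IC: ``depth(t) * (1 - log(|C(t)|+1)/log(T_total))``.

    Leaves get IC equal to their depth; the root (depth 0) gets 0.
    """
    t_total = _check_t_total(dag, namespace)
    log_t = math.log(t_total)
    ic = {}
    for t in _namespace_terms(dag, namespace):
        n_children = len(dag.children(t))
        ic[t] = dag.depth[t] * (1.0 - math.log(n_children + 1) / log_t)
    return ICTable(model="sora", ic=ic, meta={"T_total": t_total})


def ic_wis(dag: GODag, namespace: str = "BP") -> ICTable:
    """WIS structural IC.

    ``depth(t) * log|A(t)| * (1 - log(sum_{x in C(t)+{t}} 1/depth(x) + 1)
    / log(T_total))`` with ``A(t)`` the strict ancestor set.  The root is
    forced to 0 and contributes no ``1/depth`` term (its depth is 0);
    children of the root (``|A| = 1``) get 0 as the formula's literal
    consequence.
    """
    t_total = _check_t_total(dag, namespace)
    log_t = math.log(t_total)
    ic = {}
    root = dag.roots[namespace]
    for t in _namespace_terms(dag, namespace):
        if t == root:
            ic[t] = 0.0
            continue
        n_anc = len(dag.ancestors(t))
        inner = sum(
            1.0 / dag.depth[x]
            for x in (dag.children(t) | {t})
            if dag.depth[x] > 0
        )
        ic[t] = (
            dag.depth[t]
            * math.log(n_anc)
            * (1.0 - math.log(inner + 1.0) / log_t)
        )
    return ICTable(model="wis", ic=ic, meta={"T_total": t_total})


def ic_go_universal(dag: GODag, namespace: str = "BP") -> ICTable:
    """GO-universal topological IC.

    ``p(root) = 1``; ``p(t) = prod_{x in P(t)} p(x)/|C(x)|`` evaluated in
    topological order; ``IC = -log p``.
    """
    terms = _namespace_terms(dag, namespace)
    order = sorted(terms, key=lambda t: dag.depth[t])  # parents before children
    p: dict[str, float] = {}
    root = dag.roots[namespace]
    for t in order:
        if t == root:
            p[t] = 1.0
            continue
        prob = 1.0
        for parent, _ in dag.parent_edges(t):
            prob *= p[parent] / len(dag.children(parent))
        p[t] = prob
    ic = {t: -math.log(prob) for t, prob in p.items()}
    return ICTable(model="go_universal", ic=ic)


def ic_zhang(dag: GODag, namespace: str = "BP") -> ICTable:
    """Zhang descendant-mass IC.

    ``D(t) = 1`` for leaves and ``sum over children`` otherwise;
    ``p(t) = D(t)/D(root)``; ``IC = -log p``.
    """
    terms = _namespace_terms(dag, namespace)
    mass: dict[str, float] = {}
    for t in sorted(terms, key=lambda t: dag.depth[t], reverse=True):
        children = dag.children(t)
        mass[t] = sum(mass[c] for c in children) if children else 1.0
    root_mass = mass[dag.roots[namespace]]
    ic = {t: -math.log(mass[t] / root_mass) for t in terms}
    return ICTable(model="zhang", ic=ic)


@dataclass
class WangProfile:
    """Semantic-value profile of one term over its inclusive ancestors.

    ``s[x]`` is the best-path product of edge weights from ``x`` down to
    the profiled term; ``s[term] = 1``.
    """

    term: str
    s: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.s.values())


def wang_profile(
    dag: GODag,
    term_id: str,
    weights: Mapping[str, float] = DEFAULT_WANG_WEIGHTS,
) -> WangProfile:
    """Semantic values of a term's inclusive ancestors.

    ``s_t(t) = 1``; for an ancestor ``x``, ``s_t(x)`` is the maximum over
    children ``x'`` of ``x`` lying on a path to ``t`` of
    ``w(x -> x') * s_t(x')`` — the recursive best-path weight product.
    """
    t = dag.resolve(term_id)
    closure = dag.ancestors(t, inclusive=True)
    s: dict[str, float] = {t: 1.0}
    # children are strictly deeper, so descending-depth order resolves
    # every s_t(x') before it is needed
    for x in sorted(closure - {t}, key=lambda n: dag.depth[n], reverse=True):
        best = 0.0
        for child in dag.children(x):
            if child not in closure or child not in s:
                continue
            for parent, rel in dag.parent_edges(child):
                if parent == x:
                    best = max(best, weights[rel] * s[child])
        s[x] = best
    return WangProfile(term=t, s=s)


def ic_wang(
    dag: GODag,
    term_id: str,
    weights: Mapping[str, float] = DEFAULT_WANG_WEIGHTS,
) -> float:
    """Wang IC of a term: the sum of its semantic-value profile (>= 1)."""
    return wang_profile(dag, term_id, weights).total


def ic_table_wang(
    dag: GODag,
    namespace: str = "BP",
    weights: Mapping[str, float] = DEFAULT_WANG_WEIGHTS,
) -> ICTable:
    """Tabulate Wang IC for every term of a namespace."""
    ic = {
        t: ic_wang(dag, t, weights) for t in _namespace_terms(dag, namespace)
    }
    return ICTable(model="wang", ic=ic, meta=dict(weights))


def ic_table(
    model: str,
    dag: GODag,
    corpus: AnnotationCorpus | None = None,
    namespace: str | None = None,
    weights: Mapping[str, float] = DEFAULT_WANG_WEIGHTS,
) -> ICTable:
    """Dispatch to the named IC model."""
    if model == "corpus":
        if corpus is None:
            raise ValueError("corpus IC needs an annotation corpus")
        return ic_corpus(corpus)
    ns = namespace or (corpus.namespace if corpus is not None else "BP")
    if model == "sora":
        return ic_sora(dag, ns)
    if model == "wis":
        return ic_wis(dag, ns)
    if model == "go_universal":
        return ic_go_universal(dag, ns)
    if model == "zhang":
        return ic_zhang(dag, ns)
    if model == "wang":
        return ic_table_wang(dag, ns, weights)
    raise ValueError(f"unknown IC model {model!r}; expected one of {IC_MODELS}")
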