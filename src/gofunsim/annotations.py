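"""Gene annotation corpora: GAF/TSV loading and true-path propagation.

A gene annotated to a term is implicitly annotated to all of that term's
ancestors (the true-path rule).  After propagation the corpus exposes the
two counts every corpus-based and enriched IC needs: ``M(t)``, the number
of genes annotated by term ``t``, and ``N``, the total number of annotated
genes in the namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .exceptions import EmptyCorpusError, UndefinedProbabilityError, UnknownGeneError
from .ontology import GODag, NAMESPACE_CODES

logger = logging.getLogger(__name__)

_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


@dataclass
class AnnotationCorpus:
    """Propagated gene <-> term assignments for one namespace.

    Invariants: if a gene annotates ``t`` it annotates every ancestor of
    ``t``; ``M(t) = |term_genes[t]|``; ``M(root) = N``; ``M`` never
    decreases from child to parent.
    """

    namespace: str
    gene_terms: dict[str, frozenset[str]]
    term_genes: dict[str, frozenset[str]]
    direct_gene_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        """N — total annotated genes in this namespace."""
        return len(self.gene_terms)

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_terms)

    def count(self, term_id: str) -> int:
        """M(t) — number of genes annotated (after propagation) by ``t``."""
        return len(self.term_genes.get(term_id, ()))

    def terms_of(self, gene: str) -> frozenset[str]:
        try:
            return self.gene_terms[gene]
        except KeyError:
            raise UnknownGeneError(gene) from None


def parse_gaf(
    stream: IO[str] | Iterable[str],
    namespace: str,
    exclude_evidence: Iterable[str] = (),
) -> dict[str, set[str]]:
    """Read a GAF 2.x file into a raw (unpropagated) gene -> term map.

    Keeps rows whose aspect matches ``namespace`` (BP/MF/CC), drops rows
    with a NOT qualifier and rows whose evidence code is excluded.  The
    gene identifier is column 2 (DB object id).  Malformed rows are
    skipped with a logged line number.
    """
    namespace = NAMESPACE_CODES[namespace]
    exclude = set(exclude_evidence)
    raw: dict[str, set[str]] = {}
    n_kept = 0
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9 or not cols[4].startswith("GO:"):
            logger.warning("skipping malformed GAF row at line %d", lineno)
            continue
        gene, qualifier, term, evidence, aspect = (
            cols[1],
            cols[3],
            cols[4],
            cols[6],
            cols[8],
        )
        if _GAF_ASPECT.get(aspect) != namespace:
            continue
        if "NOT" in qualifier.split("|"):
            continue
        if evidence in exclude:
            continue
        raw.setdefault(gene, set()).add(term)
        n_kept += 1
    if n_kept == 0:
        raise EmptyCorpusError(f"no {namespace} associations retained from GAF input")
    return raw


def parse_tsv(stream: IO[str] | Iterable[str]) -> dict[str, set[str]]:
    """Read a plain two-column ``gene<TAB>term`` file into a raw map."""
    raw: dict[str, set[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            logger.warning("skipping malformed TSV row at line %d", lineno)
            continue
        raw.setdefault(parts[0], set()).add(parts[1])
    if not raw:
        raise EmptyCorpusError("no associations found in TSV input")
    return raw


def propagate(
    dag: GODag,
    raw: Mapping[str, Iterable[str]],
    namespace: str | None = None,
) -> AnnotationCorpus:
    """Apply true-path propagation to a raw gene -> term map.

    Each gene's term set is replaced by its inclusive ancestor closure.
    Terms unknown to the DAG (and obsolete terms) are dropped with a
    warning; genes left without any in-namespace term are excluded from N.
    """
    gene_terms: dict[str, frozenset[str]] = {}
    direct: dict[str, frozenset[str]] = {}
    ns = NAMESPACE_CODES[namespace] if namespace else None
    for gene in sorted(raw):
        kept: set[str] = set()
        closure: set[str] = set()
        for term in raw[gene]:
            try:
                tid = dag.resolve(term)
            except KeyError:
                logger.warning("dropping unknown term %s on gene %s", term, gene)
                continue
            if dag.terms[tid].obsolete:
                logger.warning("dropping obsolete term %s on gene %s", tid, gene)
                continue
            if ns is not None and dag.terms[tid].namespace != ns:
                continue
            kept.add(tid)
            closure |= dag.ancestors(tid, inclusive=True)
        if closure:
            gene_terms[gene] = frozenset(closure)
            direct[gene] = frozenset(kept)
    if not gene_terms:
        raise EmptyCorpusError("no genes with resolvable annotations")
    if ns is None:
        any_term = sorted(next(iter(gene_terms.values())))[0]
        ns = dag.terms[any_term].namespace
    term_genes: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    return AnnotationCorpus(
        namespace=ns,
        gene_terms=gene_terms,
        term_genes={t: frozenset(g) for t, g in term_genes.items()},
        direct_gene_terms=direct,
    )


def term_probability(corpus: AnnotationCorpus, term_id: str) -> float:
    """Corpus probability p(t) = M(t)/N; 1.0 at the namespace root."""
    m = corpus.count(term_id)
    if m == 0:
        raise UndefinedProbabilityError(
            f"term {term_id} annotates no gene in the corpus"
        )
    return m / corpus.n_genes
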