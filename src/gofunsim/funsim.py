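"""Gene-level functional similarity: the 46-measure registry and scoring.

A measure is an (IC model, combiner) pair.  Eleven IC/SS rows combine
with the compatible aggregation schemes:

====  ==================  =========================================
row   IC / SS             combiners
====  ==================  =========================================
U     GO-universal        ABM BMA MAX AVG DIC GIC UIC
Z     Zhang               ABM BMA MAX AVG DIC GIC UIC
W     Wang                ABM BMA MAX AVG DIC GIC UIC
N     Nunivers (corpus)   ABM BMA MAX AVG
XN    Extended Nunivers   ABM BMA MAX AVG
L     Lin (corpus)        ABM BMA MAX AVG
XL    Extended Lin        ABM BMA MAX AVG
S     Schlicker           ABM BMA MAX AVG
D     direct corpus IC    DIC GIC UIC
R     SORA                OR
I     WIS                 IUR
====  ==================  =========================================

which yields exactly 46 plain measures; each has an enriched (starred)
variant in which the query-conditional IC* replaces IC everywhere
downstream.  Genes are compared on their *propagated* term sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .annotations import AnnotationCorpus
from .enrichment import build_context, enriched_ic_table
from .exceptions import DegenerateInputError, RegistryError
from .ic import (
    DEFAULT_WANG_WEIGHTS,
    ICTable,
    ic_table,
    wang_profile,
)
from .ontology import GODag
from .termsim import pair_sim, set_ic

PAIR_COMBINERS = ("ABM", "BMA", "MAX", "AVG")
DIRECT_COMBINERS = ("DIC", "GIC", "UIC")
SET_COMBINERS = ("OR", "IUR")

#: registry rows: IC/SS acronym -> combiners valid for it
REGISTRY_ROWS: dict[str, tuple[str, ...]] = {
    "U": PAIR_COMBINERS + DIRECT_COMBINERS,
    "Z": PAIR_COMBINERS + DIRECT_COMBINERS,
    "W": PAIR_COMBINERS + DIRECT_COMBINERS,
    "N": PAIR_COMBINERS,
    "XN": PAIR_COMBINERS,
    "L": PAIR_COMBINERS,
    "XL": PAIR_COMBINERS,
    "S": PAIR_COMBINERS,
    "D": DIRECT_COMBINERS,
    "R": ("OR",),
    "I": ("IUR",),
}

#: IC model backing each row
ROW_IC_MODEL = {
    "U": "go_universal",
    "Z": "zhang",
    "W": "wang",
    "N": "corpus",
    "XN": "corpus",
    "L": "corpus",
    "XL": "corpus",
    "S": "corpus",
    "D": "corpus",
    "R": "sora",
    "I": "wis",
}

#: pairwise similarity model backing each pair-combiner row
ROW_SS_MODEL = {
    "U": "nunivers",
    "Z": "zhang_ss",
    "W": "wang",
    "N": "nunivers",
    "XN": "xnunivers",
    "L": "lin",
    "XL": "xlin",
    "S": "schlicker",
}


@dataclass(frozen=True)
class MeasureSpec:
    """Identity of one functional-similarity measure."""

    ic_model: str
    combiner: str
    enriched: bool = False

    def __post_init__(self):
        allowed = REGISTRY_ROWS.get(self.ic_model)
        if allowed is None or self.combiner not in allowed:
            rows = "; ".join(
                f"{row}: {', '.join(combs)}" for row, combs in REGISTRY_ROWS.items()
            )
            raise RegistryError(
                f"({self.ic_model}, {self.combiner}) is not a registered "
                f"measure. Valid rows — {rows}"
            )

    @property
    def name(self) -> str:
        return f"{self.ic_model}_{self.combiner}" + ("*" if self.enriched else "")

    @classmethod
    def parse(cls, text: str) -> "MeasureSpec":
        """Parse names like ``L_BMA`` or ``XN_BMA*``."""
        text = text.strip()
        enriched = text.endswith("*")
        if enriched:
            text = text[:-1]
        row, _, comb = text.partition("_")
        if not comb:
            raise RegistryError(f"cannot parse measure name {text!r}")
        return cls(ic_model=row.upper(), combiner=comb.upper(), enriched=enriched)

    @property
    def normalized(self) -> bool:
        """True when FS(g, g) = 1 is guaranteed.

        Holds for every set/direct combiner, and for MAX/BMA/ABM over
        similarities with unit self-similarity (Lin, Nunivers, Wang and
        the always-saturating Zhang pair similarity).  Excluded: AVG (a
        grand mean), the Schlicker row (sim(t, t) = 1 - e^{-IC(t)} < 1),
        the XGraSM rows (averaging over all informative common ancestors
        puts even sim(t, t) below 1), and W pair rows under enrichment
        (the enriched Wang denominator exceeds the profile total).
        """
        if self.combiner in DIRECT_COMBINERS + SET_COMBINERS:
            return True
        if self.combiner == "AVG":
            return False
        if self.ic_model in ("S", "XL", "XN"):
            return False
        if self.ic_model == "W" and self.enriched:
            return False
        return True


def list_measures(enriched_variants: bool = False) -> list[MeasureSpec]:
    """Enumerate the 46 registered measures (92 with enriched variants)."""
    specs = [
        MeasureSpec(row, comb)
        for row, combs in REGISTRY_ROWS.items()
        for comb in combs
    ]
    if enriched_variants:
        specs += [replace(s, enriched=True) for s in specs]
    return specs


@dataclass
class FSResult:
    """A scored gene pair (or disease set vs gene)."""

    genes: tuple
    measure: MeasureSpec
    score: float
    terms_used: dict = field(default_factory=dict)
    strategy: str | None = None


# ---------------------------------------------------------------------------
# combiners


def combine_direct(
    kind: str, ic: ICTable, terms1: Iterable[str], terms2: Iterable[str]
) -> float:
    """Direct term-set combiners over per-term ICs.

    GIC is the IC-weighted Jaccard index, DIC the Dice index and UIC the
    universal index.  All-root sets (both sums 0) score 1 by the
    self-similarity convention.
    """
    t1, t2 = set(terms1), set(terms2)
    s_inter = sum(ic[t] for t in t1 & t2)
    s1 = sum(ic[t] for t in t1)
    s2 = sum(ic[t] for t in t2)
    if kind == "GIC":
        denom = sum(ic[t] for t in t1 | t2)
    elif kind == "DIC":
        s_inter, denom = 2.0 * s_inter, s1 + s2
    elif kind == "UIC":
        denom = max(s1, s2)
    else:
        raise ValueError(f"unknown direct combiner {kind!r}")
    if denom == 0.0:
        return 1.0
    return s_inter / denom


def combine_pairwise(kind: str, sims: np.ndarray) -> float:
    """Aggregate a |T1| x |T2| matrix of pairwise term similarities.

    AVG is the grand mean, MAX the grand maximum, BMA the mean of the
    row-maxima averaged with the mean of the column-maxima, and ABM the
    sum of row- and column-maxima divided by |T1| + |T2|.
    """
    sims = np.asarray(sims, dtype=float)
    if sims.size == 0:
        raise DegenerateInputError("empty similarity matrix")
    if np.isnan(sims).any():
        raise DegenerateInputError("similarity matrix contains NaN")
    if kind == "AVG":
        return float(sims.mean())
    if kind == "MAX":
        return float(sims.max())
    row_max = sims.max(axis=1)
    col_max = sims.max(axis=0)
    if kind == "BMA":
        return float(0.5 * (row_max.mean() + col_max.mean()))
    if kind == "ABM":
        return float((row_max.sum() + col_max.sum()) / (sims.shape[0] + sims.shape[1]))
    raise ValueError(f"unknown pairwise combiner {kind!r}")


def combine_set(kind, set_ic_fn, terms1: Iterable[str], terms2: Iterable[str]) -> float:
    """Set-IC combiners: Overlap Ratio and Intersection-to-Union Ratio.

    ``set_ic_fn`` maps a term set to its composed IC (SORA weights for
    OR, WIS weights for IUR).  An empty intersection scores 0
    (IC of the empty set is 0 by convention).
    """
    t1, t2 = set(terms1), set(terms2)
    inter = t1 & t2
    if not inter:
        return 0.0
    ic_inter = set_ic_fn(inter)
    if kind == "OR":
        ic1, ic2 = set_ic_fn(t1), set_ic_fn(t2)
        return 0.5 * (_set_ratio(ic_inter, ic1) + _set_ratio(ic_inter, ic2))
    if kind == "IUR":
        return _set_ratio(ic_inter, set_ic_fn(t1 | t2))
    raise ValueError(f"unknown set combiner {kind!r}")


def _set_ratio(numerator: float, denominator: float) -> float:
    if denominator == 0.0:
        if numerator == 0.0:
            return 1.0
        raise DegenerateInputError("zero set IC against informative intersection")
    return numerator / denominator


# ---------------------------------------------------------------------------
# the scoring engine


class FunSimEngine:
    """Scores gene pairs under any registered measure.

    Caches per-model IC tables and Wang profiles for one (DAG, corpus)
    pair, which makes batch scoring of many pairs cheap.  ``strict``
    extends the enrichment correction to k = 0 terms.
    """

    def __init__(
        self,
        dag: GODag,
        corpus: AnnotationCorpus,
        wang_weights=DEFAULT_WANG_WEIGHTS,
        strict: bool = False,
    ):
        self.dag = dag
        self.corpus = corpus
        self.wang_weights = dict(wang_weights)
        self.strict = strict
        self._tables: dict[str, ICTable] = {}
        self._profiles: dict[str, dict[str, float]] = {}

    # -- caches --------------------------------------------------------------

    def base_table(self, model: str) -> ICTable:
        if model not in self._tables:
            self._tables[model] = ic_table(
                model,
                self.dag,
                corpus=self.corpus,
                namespace=self.corpus.namespace,
                weights=self.wang_weights,
            )
        return self._tables[model]

    def _profile(self, term: str) -> dict[str, float]:
        if term not in self._profiles:
            self._profiles[term] = wang_profile(
                self.dag, term, self.wang_weights
            ).s
        return self._profiles[term]

    # -- scoring -------------------------------------------------------------

    def score(self, spec: MeasureSpec, g1: str, g2: str) -> FSResult:
        t1 = self.corpus.terms_of(g1)
        t2 = self.corpus.terms_of(g2)
        genes = (g1,) if g1 == g2 else (g1, g2)
        table = self._table_for(spec, genes)
        value = self._score_sets(spec, t1, t2, table)
        return FSResult(
            genes=(g1, g2),
            measure=spec,
            score=value,
            terms_used={
                "common": len(t1 & t2),
                "only_first": len(t1 - t2),
                "only_second": len(t2 - t1),
            },
        )

    def _table_for(self, spec: MeasureSpec, genes: Sequence[str]) -> ICTable:
        base = self.base_table(ROW_IC_MODEL[spec.ic_model])
        if not spec.enriched:
            return base
        # duplicate query genes are collapsed: the hypergeometric draw is
        # without replacement, so a multiset query is not observable
        distinct = tuple(dict.fromkeys(genes))
        ctx = build_context(self.corpus, distinct)
        return enriched_ic_table(base, self.corpus, ctx, strict=self.strict)

    def _score_sets(
        self,
        spec: MeasureSpec,
        t1: frozenset[str],
        t2: frozenset[str],
        table: ICTable,
    ) -> float:
        comb = spec.combiner
        if comb in DIRECT_COMBINERS:
            return combine_direct(comb, table, t1, t2)
        if comb in SET_COMBINERS:
            model = ROW_IC_MODEL[spec.ic_model]  # sora for OR, wis for IUR
            fn = lambda terms: set_ic(model, self.dag, table, terms)
            return combine_set(comb, fn, t1, t2)
        # pairwise combiners
        ss = ROW_SS_MODEL[spec.ic_model]
        rows, cols = sorted(t1), sorted(t2)
        sims = np.empty((len(rows), len(cols)))
        for i, a in enumerate(rows):
            for j, b in enumerate(cols):
                if ss == "wang":
                    sims[i, j] = self._wang_sim(a, b, table)
                else:
                    sims[i, j] = pair_sim(ss, self.dag, table, a, b)
        return combine_pairwise(comb, sims)

    def _wang_sim(self, a: str, b: str, table: ICTable) -> float:
        sa, sb = self._profile(a), self._profile(b)
        common = sa.keys() & sb.keys()
        numerator = sum(sa[x] + sb[x] for x in common)
        return numerator / (table[a] + table[b])


def funsim(
    spec: MeasureSpec,
    corpus: AnnotationCorpus,
    dag: GODag,
    g1: str,
    g2: str,
    **engine_kwargs,
) -> FSResult:
    """Score one gene pair; convenience wrapper over :class:`FunSimEngine`.

    Builds a fresh engine per call — construct the engine directly when
    scoring many pairs against the same corpus.
    """
    return FunSimEngine(dag, corpus, **engine_kwargs).score(spec, g1, g2)


def disease_association(
    spec: MeasureSpec,
    corpus: AnnotationCorpus,
    dag: GODag,
    disease_genes: Sequence[str],
    candidate: str,
    strategy: str = "pool",
    engine: FunSimEngine | None = None,
) -> FSResult:
    """Associate a candidate gene with a disease gene set via FS(G_d, g).

    ``pool`` (default) unions the disease genes' propagated term sets
    into one pseudo-profile and scores it against the candidate;
    ``average`` takes the mean FS(x, g) over disease genes x.  Under
    enrichment the query context is the set of distinct genes involved
    (disease genes plus candidate), with the general hypergeometric
    correction at that query size.
    """
    if not disease_genes:
        raise DegenerateInputError("empty disease gene set")
    eng = engine or FunSimEngine(dag, corpus)
    if strategy == "average":
        scores = [eng.score(spec, x, candidate).score for x in disease_genes]
        result = FSResult(
            genes=(tuple(disease_genes), candidate),
            measure=spec,
            score=float(np.mean(scores)),
            strategy="average",
        )
        return result
    if strategy != "pool":
        raise ValueError(f"unknown disease association strategy {strategy!r}")
    pooled: frozenset[str] = frozenset().union(
        *(eng.corpus.terms_of(x) for x in disease_genes)
    )
    t_cand = eng.corpus.terms_of(candidate)
    table = eng._table_for(spec, tuple(disease_genes) + (candidate,))
    value = eng._score_sets(spec, pooled, t_cand, table)
    return FSResult(
        genes=(tuple(disease_genes), candidate),
        measure=spec,
        score=value,
        terms_used={
            "common": len(pooled & t_cand),
            "only_first": len(pooled - t_cand),
            "only_second": len(t_cand - pooled),
        },
        strategy="pool",
    )
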