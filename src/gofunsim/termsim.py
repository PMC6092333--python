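"""Pairwise semantic similarity between GO terms and IC of term sets.

Seven IC-based pairwise models (Resnik, Lin, Nunivers, Zhang, Schlicker
and the XGraSM-extended Lin/Nunivers), the Wang semantic-value
similarity, and the SORA/WIS extended-IC composition for whole term sets.

All pairwise models are driven by the common-ancestor profile of the two
terms, ordered by non-increasing IC; its head ``a0`` is the most
informative common ancestor (MICA).  Ancestor sets are inclusive of the
query terms, so ``sim(t, t) = 1`` for the normalised models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from .exceptions import (
    DegenerateInputError,
    NoComparableAncestorError,
)
from .ic import DEFAULT_WANG_WEIGHTS, ICTable, wang_profile
from .ontology import GODag

PAIR_MODELS = (
    "resnik",
    "lin",
    "nunivers",
    "zhang_ss",
    "schlicker",
    "xlin",
    "xnunivers",
)


@dataclass
class CommonAncestorProfile:
    """Common ancestors of a term pair ordered by non-increasing IC.

    ``ancestors[0]`` is the MICA; ties are broken by lexicographic term
    id so every downstream value is deterministic.
    """

    terms: tuple[str, str]
    ancestors: list[str]
    ic: list[float]

    @property
    def n(self) -> int:
        return len(self.ancestors)

    @property
    def mica(self) -> str:
        return self.ancestors[0]

    @property
    def mica_ic(self) -> float:
        return self.ic[0]


def mica(dag: GODag, ic: ICTable, t1: str, t2: str) -> CommonAncestorProfile:
    """Common-ancestor profile of two same-namespace terms.

    Common ancestors lacking an IC entry are skipped; if none remains the
    pair is not comparable under this IC model.
    """
    common = dag.common_ancestors(t1, t2)
    scored = sorted(
        ((-ic.ic[a], a) for a in common if a in ic),
        key=lambda pair: (pair[0], pair[1]),
    )
    if not scored:
        raise NoComparableAncestorError(
            f"no common ancestor of {t1} and {t2} has a {ic.model} IC entry"
        )
    return CommonAncestorProfile(
        terms=(dag.resolve(t1), dag.resolve(t2)),
        ancestors=[a for _, a in scored],
        ic=[-neg for neg, _ in scored],
    )


def _ratio_or_convention(numerator: float, denominator: float) -> float:
    """Normalised-model convention: 0/0 (both terms at IC 0) gives 1."""
    if denominator == 0.0:
        if numerator == 0.0:
            return 1.0
        raise DegenerateInputError(
            "zero-IC terms compared against an informative common ancestor"
        )
    return numerator / denominator


def _xgrasm_mean_ic(profile: CommonAncestorProfile) -> float | None:
    """Mean IC of the *informative* (IC > 0) common ancestors, or None."""
    informative = [v for v in profile.ic if v > 0.0]
    if not informative:
        return None
    return sum(informative) / len(informative)


def pair_sim(model: str, dag: GODag, ic: ICTable, t1: str, t2: str) -> float:
    """IC-based semantic similarity of a term pair under the named model.

    ``resnik`` returns the raw MICA IC; ``lin``, ``nunivers``,
    ``schlicker``, ``xlin`` and ``xnunivers`` are normalised to [0, 1];
    ``zhang_ss`` is ``exp(-IC(a0))`` — note it *decreases* with the
    common-ancestor IC, a property of the published formula kept as-is.
    The extended models average over all informative common ancestors
    (XGraSM); with no informative ancestor they fall back to the base
    Lin/Nunivers convention.
    """
    profile = mica(dag, ic, t1, t2)
    top = profile.mica_ic
    if model == "resnik":
        return top
    if model == "zhang_ss":
        return math.exp(-top)
    ic1, ic2 = ic[dag.resolve(t1)], ic[dag.resolve(t2)]
    if model == "lin":
        return _ratio_or_convention(2.0 * top, ic1 + ic2)
    if model == "nunivers":
        return _ratio_or_convention(top, max(ic1, ic2))
    if model == "schlicker":
        lin = _ratio_or_convention(2.0 * top, ic1 + ic2)
        return lin * (1.0 - math.exp(-top))
    if model in ("xlin", "xnunivers"):
        mean_ic = _xgrasm_mean_ic(profile)
        if mean_ic is None:
            mean_ic = top  # no informative ancestor: base convention
        if model == "xlin":
            return _ratio_or_convention(2.0 * mean_ic, ic1 + ic2)
        return _ratio_or_convention(mean_ic, max(ic1, ic2))
    raise ValueError(f"unknown pairwise model {model!r}; expected {PAIR_MODELS}")


def wang_sim(
    dag: GODag,
    t1: str,
    t2: str,
    weights: Mapping[str, float] = DEFAULT_WANG_WEIGHTS,
    ic: ICTable | None = None,
) -> float:
    """Wang similarity of two terms.

    Sum of both semantic values over the common inclusive ancestors,
    divided by the two Wang ICs (the profile totals).  An explicit
    ``ic`` table overrides the denominator — the hook through which the
    query-enriched Wang IC enters.
    """
    p1 = wang_profile(dag, t1, weights)
    p2 = wang_profile(dag, t2, weights)
    common = set(p1.s) & set(p2.s)
    numerator = sum(p1.s[x] + p2.s[x] for x in common)
    if ic is not None:
        denominator = ic[p1.term] + ic[p2.term]
    else:
        denominator = p1.total + p2.total
    return numerator / denominator


def set_ic(
    model: str,
    dag: GODag,
    ic: ICTable,
    terms: Iterable[str],
) -> float:
    """IC of a term set under the SORA/WIS extended-IC composition.

    Over the sub-DAG induced by the inclusive ancestor closure of the
    set, each term contributes its extended IC exactly once:
    ``IC(x) - max over in-closure parents a of w(a -> x) * IC(a)``, with
    ``w = 1`` for SORA and ``w = |C(x)|/|C(a)|`` for WIS.  Terms with no
    in-closure parent contribute their full IC.  Multi-parent terms
    credit the single largest inherited IC.
    """
    if model not in ("sora", "wis"):
        raise ValueError(f"unknown set-IC model {model!r}; expected sora|wis")
    terms = list(terms)
    if not terms:
        raise DegenerateInputError("set IC of an empty term set")
    closure: set[str] = set()
    for t in terms:
        closure |= dag.ancestors(t, inclusive=True)
    total = 0.0
    for x in closure:
        ic_x = ic[x]
        inherited = 0.0
        for a, _rel in dag.parent_edges(x):
            if a not in closure:
                continue
            if model == "sora":
                w = 1.0
            else:
                w = len(dag.children(x)) / len(dag.children(a))
            inherited = max(inherited, w * ic[a])
        total += ic_x - inherited
    return total
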