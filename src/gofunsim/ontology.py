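"""Gene Ontology DAG parsing and graph primitives.

The GO is a directed acyclic graph over terms in three namespaces
(biological process, molecular function, cellular component), connected by
``is_a``, ``part_of`` and ``regulates`` edges.  Every information-content
model and similarity measure in this package consumes the primitives
defined here: ancestor closures, children, term depth and namespace roots.

Conventions
-----------
* Depth is the number of edges on the *longest* path from the namespace
  root (root depth 0), which maximises the discrimination of depth-based
  IC models.
* All three relation types contribute to ancestry by default; the set of
  relations can be restricted at parse time (``relations=`` argument).
* ``common_ancestors`` is inclusive of the query terms themselves, so a
  term is its own most-informative common ancestor and normalised
  similarities of a term with itself are 1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

from .exceptions import (
    CrossNamespaceError,
    CycleError,
    DanglingParentError,
    OntologyError,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

#: canonical relation types; GO's positively/negatively_regulates collapse
#: onto plain ``regulates``
RELATIONS = ("is_a", "part_of", "regulates")

#: long OBO namespace names -> short codes used throughout the package
NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}
NAMESPACE_NAMES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


@dataclass
class GOTerm:
    """A single ontology term.

    ``parents`` holds ``(parent_id, relation)`` pairs; obsolete terms carry
    no parents after loading.
    """

    id: str
    name: str = ""
    namespace: str = "BP"
    parents: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


class GODag:
    """The term hierarchy with typed edges, ancestor closures and depths.

    Parameters
    ----------
    terms
        Mapping of term id to :class:`GOTerm`.  Parent references must
        resolve within the mapping and the graph must be acyclic.
    """

    def __init__(self, terms: Mapping[str, GOTerm]):
        self.terms: dict[str, GOTerm] = dict(terms)
        self.alt_ids: dict[str, str] = {}
        for t in self.terms.values():
            for a in t.alt_ids:
                self.alt_ids[a] = t.id
        self._validate_parents()
        # child -> parent multigraph over non-obsolete terms
        g = nx.MultiDiGraph()
        for t in self.terms.values():
            if t.obsolete:
                continue
            g.add_node(t.id)
            for pid, rel in t.parents:
                g.add_edge(t.id, pid, key=rel)
        self._graph = g
        self._check_acyclic()
        self.roots = self._find_roots()
        self.depth = self._compute_depths()
        self.t_total = {
            ns: sum(
                1
                for t in self.terms.values()
                if not t.obsolete and t.namespace == ns
            )
            for ns in self.roots
        }
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- construction checks -------------------------------------------------

    def _validate_parents(self) -> None:
        for t in self.terms.values():
            if t.obsolete and t.parents:
                raise OntologyError(f"obsolete term {t.id} carries parents")
            for pid, rel in t.parents:
                p = self.terms.get(pid)
                if p is None:
                    raise DanglingParentError(
                        f"term {t.id} references undefined parent {pid}"
                    )
                if p.namespace != t.namespace:
                    raise OntologyError(
                        f"edge {t.id} -> {pid} crosses namespaces "
                        f"({t.namespace} -> {p.namespace})"
                    )
                if rel not in RELATIONS:
                    raise OntologyError(
                        f"unknown relation {rel!r} on edge {t.id} -> {pid}"
                    )

    def _check_acyclic(self) -> None:
        if nx.is_directed_acyclic_graph(self._graph):
            return
        cycle = nx.find_cycle(self._graph)
        child, parent = cycle[0][0], cycle[0][1]
        raise CycleError(child, parent)

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, list[str]] = {}
        for tid in self._graph.nodes:
            if self._graph.out_degree(tid) == 0:
                roots.setdefault(self.terms[tid].namespace, []).append(tid)
        out = {}
        for ns, cands in roots.items():
            if len(cands) != 1:
                raise OntologyError(
                    f"namespace {ns} has {len(cands)} parentless terms "
                    f"({', '.join(sorted(cands))}); expected exactly one root"
                )
            out[ns] = cands[0]
        return out

    def _compute_depths(self) -> dict[str, int]:
        # longest path from the root: depth(t) = 1 + max over parents
        depth: dict[str, int] = {}
        # topological order of the child->parent graph puts parents last;
        # iterate reversed so parents are resolved first
        for tid in reversed(list(nx.topological_sort(self._graph))):
            parents = [p for _, p, _ in self._graph.out_edges(tid, keys=True)]
            depth[tid] = 1 + max(depth[p] for p in parents) if parents else 0
        return depth

    # -- lookups -------------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its canonical id; canonical ids pass through."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise UnknownTermError(term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __getitem__(self, term_id: str) -> GOTerm:
        return self.terms[self.resolve(term_id)]

    def namespace_of(self, term_id: str) -> str:
        return self[term_id].namespace

    def root(self, namespace: str) -> str:
        return self.roots[NAMESPACE_CODES[namespace]]

    def children(self, term_id: str) -> set[str]:
        """Direct children (terms whose parent list includes ``term_id``)."""
        tid = self.resolve(term_id)
        return {c for c, _, _ in self._graph.in_edges(tid, keys=True)}

    def parent_edges(self, term_id: str) -> list[tuple[str, str]]:
        """``(parent, relation)`` pairs of a term."""
        tid = self.resolve(term_id)
        return [(p, rel) for _, p, rel in self._graph.out_edges(tid, keys=True)]

    # -- closures ------------------------------------------------------------

    def ancestors(self, term_id: str, inclusive: bool = False) -> set[str]:
        """Transitive ancestor closure of a term over all relation types.

        With ``inclusive=True`` the term itself is included.
        """
        tid = self.resolve(term_id)
        if self.terms[tid].obsolete:
            raise UnknownTermError(f"{tid} is obsolete")
        if tid not in self._anc_cache:
            self._anc_cache[tid] = frozenset(nx.descendants(self._graph, tid))
        anc = set(self._anc_cache[tid])
        if inclusive:
            anc.add(tid)
        return anc

    def common_ancestors(self, t1: str, t2: str) -> set[str]:
        """Inclusive common ancestors of two same-namespace terms.

        Each term counts among its own ancestors here, so
        ``common_ancestors(t, t)`` contains ``t``; the namespace root makes
        the result non-empty for every same-namespace pair.
        """
        a, b = self.resolve(t1), self.resolve(t2)
        if self.terms[a].namespace != self.terms[b].namespace:
            raise CrossNamespaceError(
                f"{a} ({self.terms[a].namespace}) and {b} "
                f"({self.terms[b].namespace}) are in different namespaces"
            )
        return self.ancestors(a, inclusive=True) & self.ancestors(b, inclusive=True)


# ---------------------------------------------------------------------------
# OBO flat-file I/O

_REL_LINE = re.compile(r"^(\w+)\s+(\S+)")


def parse_obo(
    stream: IO[str] | Iterable[str],
    relations: Iterable[str] = RELATIONS,
) -> GODag:
    """Parse an OBO 1.2/1.4 flat file into a :class:`GODag`.

    Reads ``[Term]`` stanzas (keys: id, name, namespace, is_a,
    relationship, is_obsolete, alt_id).  Obsolete terms are retained but
    flagged, stripped of parents, and excluded from term totals and from
    the graph.  ``alt_id`` entries are mapped to their canonical id.
    ``positively_regulates``/``negatively_regulates`` collapse onto
    ``regulates``.  Relationship types outside ``relations`` are ignored
    with a logged warning.
    """
    relations = set(relations)
    terms: dict[str, GOTerm] = {}
    cur: dict | None = None

    def flush(stanza: dict | None) -> None:
        if not stanza or "id" not in stanza:
            return
        tid = stanza["id"]
        obsolete = stanza.get("obsolete", False)
        terms[tid] = GOTerm(
            id=tid,
            name=stanza.get("name", ""),
            namespace=NAMESPACE_CODES.get(stanza.get("namespace", "BP"), "BP"),
            parents=[] if obsolete else stanza.get("parents", []),
            obsolete=obsolete,
            alt_ids=tuple(stanza.get("alt_ids", ())),
        )

    in_term = False
    for raw in stream:
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush(cur if in_term else None)
            in_term = line == "[Term]"
            cur = {} if in_term else None
            continue
        if not in_term or cur is None or ":" not in line:
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "id":
            cur["id"] = value
        elif key == "name":
            cur["name"] = value
        elif key == "namespace":
            cur["namespace"] = value
        elif key == "alt_id":
            cur.setdefault("alt_ids", []).append(value)
        elif key == "is_obsolete":
            cur["obsolete"] = value.lower() == "true"
        elif key == "is_a":
            if "is_a" in relations:
                cur.setdefault("parents", []).append((value.split()[0], "is_a"))
        elif key == "relationship":
            m = _REL_LINE.match(value)
            if not m:
                continue
            rel, target = m.group(1), m.group(2)
            if rel in ("positively_regulates", "negatively_regulates"):
                rel = "regulates"
            if rel in relations and rel != "is_a":
                cur.setdefault("parents", []).append((target, rel))
            elif rel not in RELATIONS:
                logger.warning("ignoring relationship %s on %s", rel, cur.get("id"))
    flush(cur if in_term else None)

    if not terms:
        raise OntologyError("no [Term] stanzas found in OBO input")
    n_obs = sum(t.obsolete for t in terms.values())
    if n_obs:
        logger.warning("retaining %d obsolete terms (excluded from totals)", n_obs)
    return GODag(terms)


def write_obo(dag: GODag, stream: IO[str]) -> None:
    """Serialise a DAG back to OBO; inverse of :func:`parse_obo`."""
    stream.write("format-version: 1.2\nontology: gofunsim-synthetic\n")
    for tid in sorted(dag.terms):
        t = dag.terms[tid]
        stream.write(f"\n[Term]\nid: {t.id}\nname: {t.name or t.id}\n")
        stream.write(f"namespace: {NAMESPACE_NAMES[t.namespace]}\n")
        for a in t.alt_ids:
            stream.write(f"alt_id: {a}\n")
        for pid, rel in sorted(t.parents):
            if rel == "is_a":
                stream.write(f"is_a: {pid}\n")
            else:
                stream.write(f"relationship: {rel} {pid}\n")
        if t.obsolete:
            stream.write("is_obsolete: true\n")
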