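"""Shared fixtures and independent oracle helpers.

The oracle functions here deliberately avoid the package's graph and
scoring machinery: ancestor closures come from fixed-point parent
expansion over the raw term records, counts from brute-force recounting,
and similarity formulas from direct transcription.  They exist to check
the implementation, not to share code with it.
"""

from __future__ import annotations

import io

import numpy as np
import pytest

from gofunsim.annotations import parse_tsv, propagate
from gofunsim.fixtures import FixtureSpec, frozen_pair_fixture, synth_corpus, synth_dag
from gofunsim.ontology import GODag, GOTerm, parse_obo


def build_dag(edges, extra_terms=(), namespace="BP"):
    """GODag from (child, parent, relation) triples; terms are implied."""
    ids = {c for c, _, _ in edges} | {p for _, p, _ in edges} | set(extra_terms)
    terms = {i: GOTerm(id=i, name=i, namespace=namespace) for i in ids}
    for child, parent, rel in edges:
        terms[child].parents.append((parent, rel))
    return GODag(terms)

# ---------------------------------------------------------------------------
# oracles


def oracle_ancestors(terms, t, inclusive=False):
    """Fixed-point parent expansion over raw GOTerm records."""
    out = {t} if inclusive else set()
    frontier = {p for p, _ in terms[t].parents}
    while frontier:
        out |= frontier
        frontier = {
            p for x in frontier for p, _ in terms[x].parents
        } - out
    return out


def oracle_closure(terms, annotated):
    """Inclusive closure of a set of directly annotated terms."""
    out = set()
    for t in annotated:
        out |= oracle_ancestors(terms, t, inclusive=True) if t in terms else set()
    return out


# ---------------------------------------------------------------------------
# tiny hand-built ontologies


CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: mid
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
relationship: part_of GO:0000002
"""

#: root with two internal parents sharing two bottom children (diamond)
DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: left
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: right
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: bottom
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003

[Term]
id: GO:0000005
name: bottom2
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003
"""

#: the worked toy corpus: root, one parent p with two children t1, t2;
#: four genes give M(root)=4, M(p)=2, M(t1)=M(t2)=1
TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: p
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: t1
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000004
name: t2
namespace: biological_process
is_a: GO:0000002
"""

TOY_TSV = """\
g1\tGO:0000003
g2\tGO:0000004
g3\tGO:0000001
g4\tGO:0000001
"""


@pytest.fixture
def chain_dag():
    return parse_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def diamond_dag():
    return parse_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture
def toy():
    """(dag, corpus) with N=4; M: root 4, p 2, t1 1, t2 1."""
    dag = parse_obo(io.StringIO(TOY_OBO))
    corpus = propagate(dag, parse_tsv(io.StringIO(TOY_TSV)), namespace="BP")
    return dag, corpus


@pytest.fixture
def frozen():
    """The shipped 7-term / 4-gene worked example."""
    return frozen_pair_fixture()


def small_study(seed, **overrides):
    """A random toy DAG + corpus, sized for oracle comparisons."""
    defaults = dict(n_terms=30, n_levels=4, n_genes=12, annotations_per_gene=3.0)
    defaults.update(overrides)
    spec = FixtureSpec(seed=seed, **defaults)
    dag = synth_dag(spec)
    corpus = synth_corpus(dag, spec)
    return dag, corpus


@pytest.fixture
def rng():
    return np.random.default_rng(20180814)
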