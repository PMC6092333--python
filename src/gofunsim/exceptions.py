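"""Exception hierarchy for gofunsim.

Every error raised on bad user input derives from :class:`GofunsimError`,
so callers (and the CLI) can catch one type and turn it into a diagnostic.
"""


class GofunsimError(Exception):
    """Base class for all gofunsim errors."""


class OntologyError(GofunsimError):
    """Structural problem in an ontology file or graph."""


class CycleError(OntologyError):
    """The term graph contains a directed cycle; names one offending edge."""

    def __init__(self, child: str, parent: str):
        self.edge = (child, parent)
        super().__init__(
            f"ontology graph is cyclic: edge {child} -> {parent} closes a cycle"
        )


class DanglingParentError(OntologyError):
    """A term references a parent id that is not defined anywhere."""


class UnknownTermError(GofunsimError, KeyError):
    """Lookup of a term id that does not exist in the DAG."""


class CrossNamespaceError(GofunsimError):
    """Two terms from different GO namespaces were compared."""


class EmptyCorpusError(GofunsimError):
    """No annotations survived parsing/filtering."""


class UnknownGeneError(GofunsimError, KeyError):
    """A query gene is absent from the annotation corpus."""


class UndefinedProbabilityError(GofunsimError):
    """Corpus probability requested for a term with zero annotation count."""


class DegenerateDagError(GofunsimError):
    """The DAG is too small for a structure-based IC model (T_total <= 1)."""


class DegenerateInputError(GofunsimError):
    """A similarity formula hit a division by zero outside its conventions."""


class NoComparableAncestorError(GofunsimError):
    """No common ancestor of a term pair carries an IC entry."""


class InconsistentContextError(GofunsimError):
    """An (k, n, M, N) annotation context has hypergeometric probability 0."""


class RegistryError(GofunsimError):
    """An (IC model, combiner) pair outside the measure registry."""
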