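"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`CoexnetError`, so callers can catch one type at a pipeline
boundary.  Errors that are also programming-contract violations subclass
the matching builtin (``ValueError``/``KeyError``) so idiomatic ``except``
clauses keep working.
"""


class CoexnetError(Exception):
    """Base class for all errors raised by coexnet."""


class ParseError(CoexnetError, ValueError):
    """A table cell could not be parsed; message carries row/column coordinates."""


class DuplicateLabelError(CoexnetError, ValueError):
    """A row or column label occurs more than once; message names the label."""


class DegenerateTraitError(CoexnetError, ValueError):
    """A trait has fewer than the minimum number of non-missing strains."""


class AlignmentError(CoexnetError, ValueError):
    """Expression and phenotype tables share no strains."""


class ShapeError(CoexnetError, ValueError):
    """Vector/matrix dimensions do not match."""


class DomainError(CoexnetError, ValueError):
    """A numeric argument lies outside its allowed domain."""


class UnknownNodeError(CoexnetError, KeyError):
    """A node id is not present in the network / matrix."""


class ConvergenceError(CoexnetError, RuntimeError):
    """An iterative solver did not converge; message reports the last residual."""


class DivergenceError(CoexnetError, RuntimeError):
    """A layout optimisation produced a non-finite objective."""


class DegenerateDistributionError(CoexnetError, ValueError):
    """Degree distribution requested on a graph with no edges."""


class InsufficientPointsError(CoexnetError, ValueError):
    """Too few distinct degree values for a log-log fit."""


class SelectionError(CoexnetError, ValueError):
    """No scanned threshold satisfied the scale-free selection rule."""


class CapacityError(CoexnetError, ValueError):
    """Grid has fewer cells than there are nodes to place."""


class ConfigError(CoexnetError, ValueError):
    """Invalid pipeline or generator configuration."""


class UndefinedResultError(CoexnetError, ValueError):
    """A statistic is undefined for this input (e.g. no reachable pair)."""
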