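"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` (and subclasses)
exit with status 2, :class:`DegenerateInputError` with status 3.
"""


class ComplexModError(Exception):
    """Base class for all package-specific errors."""


class InputError(ComplexModError):
    """Unreadable, malformed or otherwise unusable input."""


class ParseError(InputError):
    """A structure or graph file could not be parsed."""


class EmptyStructureError(InputError):
    """A structure contains no polypeptide chain, so no graph can be built."""


class GeneratorError(InputError):
    """A synthetic-fixture specification violates its own guarantees."""


class DegenerateInputError(ComplexModError):
    """Input is syntactically fine but too small/degenerate for the operation."""


class SizeGuardError(ComplexModError):
    """Exhaustive enumeration requested on a graph too large to enumerate."""
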