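"""Exception hierarchy.

Every error raised by the library derives from :class:`MirCascadeError`, so
callers (and the CLI) can catch one type.  Subclasses also derive from the
closest builtin so generic ``except ValueError`` style code keeps working.
"""


class MirCascadeError(Exception):
    """Base class for all mircascade errors."""


class FormatError(MirCascadeError, ValueError):
    """A file does not conform to the expected CSV layout."""


class ValidationError(MirCascadeError, ValueError):
    """A value violates a documented domain constraint."""


class NotFoundError(MirCascadeError, KeyError):
    """A requested node / record does not exist."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class InfeasibleError(MirCascadeError, RuntimeError):
    """The edge-weight linear program has no feasible point."""


class ResourceError(MirCascadeError, RuntimeError):
    """An exact computation would exceed its enumeration guard."""
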