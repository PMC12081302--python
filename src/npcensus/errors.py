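"""Exception hierarchy shared across the package."""


class NPCensusError(Exception):
    """Base class for all package errors."""


class ParameterError(NPCensusError, ValueError):
    """An argument is outside its documented domain."""


class GeometryError(NPCensusError):
    """Input geometry is degenerate or inconsistent (e.g. phantom exceeds box)."""


class DegenerateInputError(NPCensusError):
    """Input is formally valid but carries no usable signal (e.g. constant score volume)."""


class EmptySetError(NPCensusError):
    """An operation that needs at least one element received none."""
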