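"""Exception hierarchy.

Each CLI-facing failure class maps to a distinct process exit code
(see :mod:`membpka.cli`).
"""


class MembPkaError(Exception):
    """Base class for all package errors."""


class ParseError(MembPkaError):
    """A structure or table file could not be parsed."""


class ParameterLookupError(MembPkaError):
    """A residue/atom is missing from a charge/radius parameter table."""


class GeometryError(MembPkaError):
    """Membrane geometry could not be estimated from the frame."""


class IonClassificationError(MembPkaError):
    """An ion species is not present in the valence table."""


class SolverError(MembPkaError):
    """The linear PB solve failed to converge."""


class FitError(MembPkaError):
    """A nonlinear fit failed or was given degenerate data."""


class ToySpecError(MembPkaError):
    """A synthetic-system specification is internally inconsistent."""
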