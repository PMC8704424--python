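"""Exception hierarchy shared across the pipeline.

CLI exit codes: SchemaError -> 2, IntegrityError -> 3, SolverError -> 4,
everything else -> 1.
"""


class StimlimitError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(StimlimitError):
    """Electrode geometry is unphysical (e.g. non-positive diameter)."""


class InvalidParameterError(StimlimitError):
    """A numeric parameter is out of its valid range."""


class FormatError(StimlimitError):
    """An input record violates its format contract (e.g. non-monotone time)."""


class ResolutionError(StimlimitError):
    """Sampling too coarse for the requested measurement."""


class ProtocolError(StimlimitError):
    """Stimulus structure absent or inconsistent with the declared protocol."""


class BelowResolutionError(StimlimitError):
    """Even the smallest probe already exceeds the electrochemical limits."""


class DomainError(StimlimitError):
    """Requested point lies outside the conductive domain."""


class SolverError(StimlimitError):
    """Linear solve failed or did not reach the requested residual."""


class BaselineError(StimlimitError):
    """Pre-stimulus baseline missing or shorter than required."""


class InputError(StimlimitError):
    """Empty or structurally unusable analysis input."""


class SchemaError(StimlimitError):
    """Configuration or table header fails schema validation."""


class IntegrityError(StimlimitError):
    """Referential integrity violated between joined tables."""
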