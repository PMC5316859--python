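"""Exception hierarchy.

All package-specific failures derive from :class:`NanoFTIRError` so callers
can catch one base class; input-contract violations additionally derive from
:class:`ValueError`.
"""


class NanoFTIRError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NanoFTIRError, ValueError):
    """An argument violates a documented precondition."""


class GridMismatchError(InvalidInputError):
    """Two objects that must share a frequency grid do not."""


class BoundaryError(NanoFTIRError, RuntimeError):
    """Stage drift carried the scan outside the scene margin."""


class DegenerateReferenceError(NanoFTIRError, RuntimeError):
    """Reference spectrum amplitude is ~0 on the band support."""


class FlatImageError(InvalidInputError):
    """Image has zero variance; cross-correlation is undefined."""


class UndefinedCorrelationError(InvalidInputError):
    """A spectrum has zero variance; Pearson correlation is undefined."""


class UnsupportedBandConfigError(InvalidInputError):
    """More than two band supports overlap at one frequency."""


class SchemaError(NanoFTIRError, RuntimeError):
    """HDF5 file does not match the expected cube layout/version."""
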