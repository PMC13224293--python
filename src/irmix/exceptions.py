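"""Exception hierarchy for irmix.

All library errors derive from :class:`IrmixError` so callers can catch one
base type at the CLI boundary.
"""


class IrmixError(Exception):
    """Base class for all irmix errors."""


class InvalidInputError(IrmixError, ValueError):
    """Malformed input data (too few points, bad shapes, ...)."""


class InvalidParameterError(IrmixError, ValueError):
    """A parameter violates its documented range."""


class IncompatibleGridsError(IrmixError, ValueError):
    """Two spectra do not share the same wavenumber grid."""


class NotNormalizedError(IrmixError, ValueError):
    """An operation requiring unit-area spectra received an unnormalized one."""


class DegenerateSpectrumError(IrmixError, ValueError):
    """A spectrum with zero total intensity where positive mass is required."""


class AliasingError(IrmixError, ValueError):
    """Requested wavenumbers exceed the Nyquist limit of a dipole trajectory."""


class InvalidBasisError(IrmixError, ValueError):
    """A basis set violates its invariants (empty, duplicate ids, ...)."""


class UnknownComponentError(IrmixError, KeyError):
    """A component id is absent from the library or basis."""


class MissingMetadataError(IrmixError, ValueError):
    """Required metadata (e.g. a molecular formula) is missing."""


class InvalidConfigurationError(IrmixError, ValueError):
    """A run configuration is internally inconsistent."""


class FormulaParseError(IrmixError, ValueError):
    """A molecular formula string could not be parsed."""


class SchemaValidationError(IrmixError, ValueError):
    """A serialized library or report violates its schema."""


class FormatError(IrmixError, ValueError):
    """A text file (CSV spectrum, ...) violates its format contract."""


class AdapterError(IrmixError, ValueError):
    """An external-dataset adapter mapping is incomplete or inconsistent."""
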