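"""Exception hierarchy."""


class OrientScanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OrientScanError):
    """Invalid body/sub-group assignment or run configuration."""


class ParameterizationError(OrientScanError):
    """A residue or atom could not be matched to the parameter table."""


class GeometryError(OrientScanError):
    """Degenerate geometry (no unique principal axis, empty body, ...)."""


class SingularityError(OrientScanError):
    """Overlapping atoms in a pairwise energy evaluation."""


class DegenerateProfileError(OrientScanError):
    """Every pose of a scan was masked by the clash filter."""


class UndefinedCorrelationError(OrientScanError):
    """Correlation requested for a zero-variance or too-short vector."""


class UndefinedRadiusError(OrientScanError):
    """Born radius requested for a zero-charge atom."""
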