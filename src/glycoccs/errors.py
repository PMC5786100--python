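"""Exception hierarchy.

Every error raised by this package derives from :class:`GlycoCCSError`,
so callers can catch one type at pipeline boundaries while the leaf
classes keep failure modes distinguishable in tests and logs.
"""


class GlycoCCSError(Exception):
    """Base class for all glycoccs errors."""


class ParseError(GlycoCCSError):
    """A file could not be parsed in the declared format."""


class StructuralInconsistencyError(GlycoCCSError):
    """Conformers of one ensemble disagree on atom count or order."""


class CoverageError(GlycoCCSError):
    """A sidecar table (charges, annotation) does not cover every atom/residue."""


class AnnotationError(GlycoCCSError):
    """Residue annotation conflict or unknown structural-unit label."""


class CalibrationError(GlycoCCSError):
    """Calibration cannot be fitted (singular or insufficient data)."""


class ParameterError(GlycoCCSError):
    """A required gas/element interaction parameter is missing."""


class GeometryError(GlycoCCSError):
    """Degenerate or physically impossible geometry."""


class DomainError(GlycoCCSError):
    """An input value is outside the physically meaningful domain."""


class ConfigError(GlycoCCSError):
    """Pipeline configuration is malformed or contains unknown keys."""
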