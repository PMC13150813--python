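"""Exception hierarchy shared across the package."""


class MetabosimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MetabosimError, ValueError):
    """Input violates a documented precondition or invariant."""


class ComplexityError(MetabosimError):
    """Spin system too large for exact quantum-mechanical simulation."""


class ParseError(MetabosimError, ValueError):
    """Malformed spin-matrix XML or STAR text."""


class SchemaError(ParseError):
    """Well-formed STAR file that violates the entry dialect schema."""


class UndefinedScoreError(MetabosimError, ValueError):
    """Cosine score undefined (a zero vector was supplied)."""


class UndefinedSNRError(MetabosimError, ValueError):
    """Signal-to-noise undefined (noise region has zero deviation)."""


class EmptyReportError(MetabosimError):
    """No region of interest survived exclusion; no score can be reported."""


class AlignmentError(MetabosimError):
    """Offset alignment impossible (e.g. featureless experimental grid)."""


class OptimizationError(MetabosimError):
    """Width-scale (or other 1-D) optimization produced non-finite scores."""
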