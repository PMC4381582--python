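"""Exception hierarchy shared across the pipeline."""


class SylScreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SylScreenError):
    """Input table violates the expected schema (e.g. missing column)."""


class IntegrityError(SylScreenError):
    """Input values violate dataset invariants (duplicates, negatives)."""


class NormalizationError(SylScreenError):
    """A plate cannot be normalized (no or degenerate negative controls)."""


class InsufficientDataError(SylScreenError):
    """Too few points/wells for the requested computation."""


class FitError(SylScreenError):
    """Nonlinear fit failed to converge from every start."""


class GridMismatchError(SylScreenError):
    """Two titrations share no common concentration grid."""


class DegenerateAssayError(SylScreenError):
    """Assay controls do not separate (high control <= low control)."""


class ConfigError(SylScreenError):
    """Invalid simulation or analysis configuration."""
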