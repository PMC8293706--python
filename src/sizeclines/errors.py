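"""Exception types shared across the package."""


class SizeclinesError(Exception):
    """Base class for package-specific errors."""


class InvalidGridError(SizeclinesError, ValueError):
    """Grid specification is unusable (non-positive dimensions, bad bounds)."""


class MissingSpeciesError(SizeclinesError, KeyError):
    """Species referenced in one table are absent from another."""


class AlignmentError(SizeclinesError, ValueError):
    """Species sets of two inputs (tree, traits, climate) do not match."""


class RankDeficiencyError(SizeclinesError, ValueError):
    """Design matrix is rank deficient; offending columns are listed."""


class EmptyAnalysisError(SizeclinesError, ValueError):
    """A filtering step left no rows to analyze."""


class NestingViolationError(SizeclinesError, ValueError):
    """A genus appears under more than one family."""


class AllometryError(SizeclinesError, ValueError):
    """Allometric coefficients are missing or degenerate."""
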