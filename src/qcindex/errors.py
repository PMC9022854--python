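"""Exception hierarchy for the qcindex pipeline.

Every stage raises a subclass of :class:`QCIndexError`, so callers (notably
the command-line pipeline) can map failures onto a stable exit-code contract:
configuration problems, data problems, and degenerate-math problems are
distinguishable without string matching.
"""


class QCIndexError(Exception):
    """Base class for all qcindex errors."""


class ConfigError(QCIndexError):
    """Invalid configuration: bad enum value, non-monotone cutpoints,
    invalid distribution parameters, unresolvable path."""


class SchemaError(QCIndexError):
    """Input table is missing a required column or has an unusable header."""


class ValidationError(QCIndexError):
    """Input table violates a value-level invariant (negative or non-finite
    value, out-of-range sex/measure label)."""


class DuplicateKeyError(ValidationError):
    """The same (location, year, sex, age_group, measure) key appears twice
    in a table read in strict mode."""


class CoverageError(QCIndexError):
    """An age standard references an age group absent from the rate series."""


class InsufficientDataError(QCIndexError):
    """Too few strata to fit, correlate, or rank (e.g. < 3 rows for PCA,
    < 5 locations for rank quintiles, empty join)."""


class DegenerateInputError(QCIndexError):
    """Mathematically degenerate input: zero-variance ratio column,
    zero-spread raw scores (score_max == score_min), all-zero loadings."""
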