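"""Exception hierarchy for deuteromics.

Every error raised by the library derives from :class:`DeuteromicsError`,
so callers can catch one base class at pipeline boundaries while tests
can assert on the specific failure mode.
"""


class DeuteromicsError(Exception):
    """Base class for all deuteromics errors."""


class TableFormatError(DeuteromicsError):
    """A tabular input does not conform to the expected dialect
    (e.g. a mandatory column is missing)."""


class IntegrityError(DeuteromicsError):
    """Duplicate identifiers or other uniqueness violations."""


class NormalizationError(DeuteromicsError):
    """TPM normalization cannot be performed (e.g. all counts zero)."""


class StatisticError(DeuteromicsError):
    """A statistic is undefined for the given input
    (zero total weight, empty sets, all pairs degenerate, ...)."""


class ConfigError(DeuteromicsError):
    """A generator or pipeline configuration is invalid or infeasible."""


class FitError(DeuteromicsError):
    """A model fit cannot be computed (too few points, degenerate design)."""


class ComparisonError(DeuteromicsError):
    """A two-fit or two-distribution comparison is undefined."""
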