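"""Exception hierarchy for the pipeline.

All errors raised deliberately by this package derive from
:class:`GnotofuncError` so callers can catch them with a single clause.
"""


class GnotofuncError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GnotofuncError):
    """An input file or definition string could not be parsed."""


class ConfigurationError(GnotofuncError):
    """A configuration value or rule file is invalid."""


class ParameterError(GnotofuncError):
    """A generator or analysis parameter is unachievable or out of range."""


class DegenerateModuleError(GnotofuncError):
    """A module has no non-optional steps, so coverage is undefined."""


class DegenerateTableError(GnotofuncError):
    """A contingency table has an expected cell of zero (or too few rows/columns)."""


class DegenerateBackgroundError(GnotofuncError):
    """The background gene-score pool has zero variance."""


class UndefinedIndexError(GnotofuncError):
    """A dissimilarity index is requested for fewer than two members."""
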