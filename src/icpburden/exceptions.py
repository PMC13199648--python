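"""Exception hierarchy shared across the package."""


class IcpBurdenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IcpBurdenError, ValueError):
    """A table is structurally malformed (missing column, duplicate key)."""


class ParseError(IcpBurdenError, ValueError):
    """A cell cannot be interpreted (non-numeric, negative time, NaN)."""


class UnusableTraceError(IcpBurdenError, ValueError):
    """A trace has no contiguous segment of at least two samples."""


class UndefinedMetricError(IcpBurdenError, ValueError):
    """A burden metric is undefined for this input (e.g. max ICP <= 0)."""


class DegenerateDataError(IcpBurdenError, ValueError):
    """A statistical test cannot be computed (zero variance, single class)."""


class ConfigError(IcpBurdenError, ValueError):
    """Invalid or contradictory run configuration."""
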