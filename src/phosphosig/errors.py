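"""Exception hierarchy shared across the package.

Error classes map onto CLI exit codes: configuration problems (bad design,
unknown comparison), format problems (malformed input tables) and statistic
problems (degenerate inputs to an estimator) are distinguished so callers
can react programmatically.
"""


class PhosphosigError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(PhosphosigError):
    """Invalid experiment design, pipeline config or comparison request."""

    exit_code = 2


class FormatError(PhosphosigError):
    """An input table violates the expected format."""

    exit_code = 3


class StatisticError(PhosphosigError):
    """A statistical routine received degenerate input (e.g. zero spread)."""

    exit_code = 4


class DegenerateSetError(StatisticError):
    """A gene/site set is empty or spans the whole ranked universe."""
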