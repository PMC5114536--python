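"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2,
data/schema/alignment problems exit 3.
"""


class TknetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TknetError, ValueError):
    """Invalid configuration: unknown keys, type mismatches, out-of-range thresholds."""


class DataError(TknetError, ValueError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A table is missing required columns or has malformed cells."""


class AlignmentError(DataError):
    """Sample sets of jointly analysed tables do not match."""


class DegenerateInputError(DataError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
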