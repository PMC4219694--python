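"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
DegenerateStatisticsWarning escalated under --strict -> 4.
"""


class UcevarError(Exception):
    """Base class for package errors."""


class ConfigError(UcevarError):
    """Invalid run configuration (bad paths, inconsistent thresholds)."""


class DataError(UcevarError):
    """Input data violates a precondition (malformed records, empty samples)."""


class BedParseError(DataError):
    """A BED/genome file line could not be parsed; message carries line number."""


class DegenerateStatisticsWarning(UserWarning):
    """A statistic could not be computed meaningfully (e.g. empty feature set)."""
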