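"""Exception hierarchy.

Three broad classes map onto distinct CLI exit codes: configuration
problems (the user asked for something invalid), data problems (an input
table violates a contract), and parse problems (a file could not even be
read into a table).
"""


class FamriskError(Exception):
    """Base class for all package errors."""


class ConfigError(FamriskError):
    """Invalid configuration; the message names the offending field."""


class DataError(FamriskError):
    """An input table or graph violates a structural contract."""


class ParseError(DataError):
    """A file on disk could not be parsed; the message carries row context."""


class PedigreeError(DataError):
    """Pedigree-specific structural violation (cycles, sex-inconsistent parents)."""


class CohortRateError(DataError):
    """A cohort required for expected-count computation has no estimated rate."""
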