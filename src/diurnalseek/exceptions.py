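"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
DegenerateDataError -> 4.
"""


class DiurnalSeekError(Exception):
    """Base class for all package errors."""


class ConfigError(DiurnalSeekError):
    """Invalid configuration value or violated config invariant."""


class DataError(DiurnalSeekError):
    """Malformed, inconsistent, or insufficient input data."""


class ParseError(DataError):
    """A cell or timestamp could not be parsed; names the offending row."""


class ValidationError(DataError):
    """A parsed value violates the data model (e.g. RSV outside [0, 100])."""


class SpacingError(DataError):
    """Timestamps are not on a uniform hourly grid; lists gap locations."""


class GapError(DataError):
    """Unrepairable gap between or within series segments."""


class DuplicateTimestampError(DataError):
    """The same hourly instant appears more than once."""


class DegenerateDataError(DiurnalSeekError):
    """Statistical procedure undefined on this input (e.g. zero variance)."""


class EmptyBandError(ConfigError):
    """A period band that selects no wavelet scales."""
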